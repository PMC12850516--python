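import numpy as np
import pytest

from seizpipe import eeg_features, synthgen


@pytest.fixture(scope="session")
def small_dataset():
    """40 balanced records, 22 channels, 8 s at 256 Hz, 10 subjects."""
    return synthgen.generate_eeg_dataset(
        n_samples=40, n_channels=22, fs=256.0, duration_s=8.0, seed=7, n_subjects=10
    )


@pytest.fixture(scope="session")
def fitted_bank(small_dataset):
    return eeg_features.fit_ecsp(small_dataset)


@pytest.fixture(scope="session")
def phantom_pair():
    clean = synthgen.generate_brain_phantom((32, 32), lesion=False, seed=11)
    lesioned = synthgen.generate_brain_phantom((32, 32), lesion=True, seed=11)
    return clean, lesioned


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
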
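"""Spectral/temporal descriptors and the enhanced CSP chain."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from seizpipe import eeg_features as ef
from seizpipe.synthgen import EEGRecord


def make_record(data, fs=256.0, label=0):
    return EEGRecord(data=np.atleast_2d(data), fs=fs, label=label, subject_id="s0")


class TestBandPowers:
    def test_zero_signal(self):
        rec = make_record(np.zeros((3, 1024)))
        np.testing.assert_allclose(ef.band_powers(rec), 0.0)

    def test_pure_alpha_sine_concentrates(self):
        t = np.arange(2048) / 256.0
        rec = make_record(np.sin(2 * np.pi * 10.0 * t))
        p = ef.band_powers(rec)[0]
        assert p[2] / p.sum() > 0.9  # alpha band

    def test_white_noise_power_tracks_bandwidth(self, rng):
        x = rng.standard_normal(256 * 60)
        rec = make_record(x)
        powers = ef.band_powers(rec)[0]
        widths = np.array([3.5, 4.0, 5.0, 17.0, 50.0])
        density = powers / widths
        assert np.abs(density / density.mean() - 1).max() < 0.1


class TestTemporalDescriptors:
    def test_constant_channel_guards(self):
        rec = make_record(np.full((2, 100), 3.0))
        d = ef.temporal_descriptors(rec)
        np.testing.assert_allclose(d, 0.0)

    def test_unit_sine_activity(self):
        t = np.arange(256 * 32) / 256.0
        rec = make_record(np.sin(2 * np.pi * 7.0 * t))
        activity = ef.temporal_descriptors(rec)[0, 0]
        assert activity == pytest.approx(0.5, abs=1e-3)

    def test_sine_zero_crossing_rate(self):
        fs, T, f = 256.0, 8.0, 6.0
        t = np.arange(int(fs * T)) / fs
        rec = make_record(np.sin(2 * np.pi * f * t + 0.3))
        zcr = ef.temporal_descriptors(rec)[0, 4]
        assert abs(zcr * T - 2 * f * T) <= 1.0

    def test_line_length_of_sawtooth(self):
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        rec = make_record(x, fs=5.0)
        assert ef.temporal_descriptors(rec)[0, 3] == pytest.approx(4.0)


class TestSpectralRolloff:
    def test_sine_rolls_off_at_tone(self):
        t = np.arange(4096) / 256.0
        f0 = 20.0
        r = ef.spectral_rolloff(np.sin(2 * np.pi * f0 * t), 256.0, 0.85)
        assert abs(r - f0) <= 0.5  # one Welch bin

    def test_white_noise_rolloff_near_pct_nyquist(self, rng):
        x = rng.standard_normal(256 * 120)
        r = ef.spectral_rolloff(x, 256.0, 0.85)
        assert abs(r - 0.85 * 128.0) / (0.85 * 128.0) < 0.05

    def test_pct_one_unreachable(self):
        with pytest.raises(ValueError):
            ef.spectral_rolloff(np.ones(100), 10.0, 1.0)

    def test_zero_signal_flagged_zero(self):
        with pytest.warns(UserWarning):
            assert ef.spectral_rolloff(np.zeros(1024), 256.0) == 0.0


class TestActivation:
    def test_rest_mean_maps_to_zero(self, rng):
        rest = rng.standard_normal((2, 200))
        task = np.full((2, 10), rest.mean())
        np.testing.assert_allclose(ef.ecsp_activate(task, rest), 0.0, atol=1e-12)

    def test_output_bounded(self, rng):
        rest = rng.standard_normal((3, 100))
        task = rng.standard_normal((3, 100)) * 1e3
        out = ef.ecsp_activate(task, rest)
        assert (out > -0.27).all() and (out < 1.0).all()

    def test_chain_monotone(self):
        rest = np.sin(np.arange(100.0)).reshape(1, -1)
        grid = np.linspace(-50, 50, 2001).reshape(1, -1)
        out = ef.ecsp_activate(grid, rest)
        assert (np.diff(out[0]) >= 0).all()

    def test_constant_rest_rejected(self):
        with pytest.raises(ValueError):
            ef.ecsp_activate(np.ones((2, 5)), np.ones((2, 5)))


class TestFrequencyWeight:
    @pytest.mark.parametrize(
        "f,expected", [(5.0, 1.0), (3.0, 0.5), (7.0, 0.5), (9.0, 0.2), (1.0, 0.2)]
    )
    def test_reference_points(self, f, expected):
        assert ef.frequency_weight(f, fc=5.0, delta_f=4.0) == pytest.approx(expected)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            ef.frequency_weight(1.0, 1.0, 0.0)


class TestCovariances:
    def make_trials(self, rng, n=6, c=4, t=512):
        trials = [rng.standard_normal((c, t)) for _ in range(n)]
        labels = np.array([0, 1] * (n // 2))
        return trials, labels

    def test_shrinkage_algebra(self, rng):
        trials, labels = self.make_trials(rng)
        base = ef.ecsp_covariances(trials, labels, ef.ECSPParams(gamma1=0.0, gamma2=0.0))
        shrunk = ef.ecsp_covariances(trials, labels, ef.ECSPParams(gamma1=0.3, gamma2=0.3))
        J = np.eye(4)
        np.testing.assert_allclose(
            shrunk.G1_shrunk, 0.7 * base.G1_shrunk + 0.3 * J, atol=1e-12
        )

    def test_full_shrinkage_gives_identity(self, rng):
        trials, labels = self.make_trials(rng)
        cov = ef.ecsp_covariances(trials, labels, ef.ECSPParams(gamma1=1.0, gamma2=1.0))
        np.testing.assert_allclose(cov.G1_shrunk, np.eye(4))
        np.testing.assert_allclose(cov.G2_shrunk, np.eye(4))

    def test_scalar_mode_unit_weight_is_sample_covariance(self, rng):
        # trials whose dominant frequency sits exactly at fc get weight 1
        fs, fc = 256.0, 8.0
        t = np.arange(512) / fs
        trials = [
            np.sin(2 * np.pi * fc * t[None, :] + rng.uniform(0, 6, (3, 1)))
            + 0.01 * rng.standard_normal((3, 512))
            for _ in range(4)
        ]
        labels = np.array([0, 1, 0, 1])
        params = ef.ECSPParams(gamma1=0.0, gamma2=0.0, fc=fc, weight_mode="scalar")
        cov = ef.ecsp_covariances(trials, labels, params, fs=fs)
        expected = np.mean([tr @ tr.T / tr.shape[1] for tr, l in zip(trials, labels) if l == 1], axis=0)
        np.testing.assert_allclose(cov.G1_shrunk, expected, atol=1e-10)

    def test_symmetric_psd_output(self, rng):
        trials, labels = self.make_trials(rng)
        cov = ef.ecsp_covariances(trials, labels)
        for G in (cov.G1_shrunk, cov.G2_shrunk):
            np.testing.assert_allclose(G, G.T, atol=1e-12)
            assert np.linalg.eigvalsh(G).min() >= -1e-10

    def test_missing_class_rejected(self, rng):
        trials, _ = self.make_trials(rng)
        with pytest.raises(ValueError):
            ef.ecsp_covariances(trials, np.ones(len(trials)))


class TestFilters:
    def test_diagonal_toy_recovers_axes(self):
        cov = ef.ECSPCovariances(np.diag([4.0, 1.0]), np.diag([1.0, 4.0]))
        bank = ef.ecsp_filters(cov, 2)
        np.testing.assert_allclose(sorted(bank.eigenvalues), [0.25, 4.0])
        np.testing.assert_allclose(np.abs(bank.filters), np.eye(2), atol=1e-10)

    def test_rayleigh_quotient_matches_eigenvalue(self, rng):
        A = rng.standard_normal((5, 5))
        B = rng.standard_normal((5, 5))
        cov = ef.ECSPCovariances(A @ A.T + 0.1 * np.eye(5), B @ B.T + 0.1 * np.eye(5))
        bank = ef.ecsp_filters(cov, 4)
        for w, lam in zip(bank.filters, bank.eigenvalues):
            assert ef.ecsp_objective(cov, w) == pytest.approx(lam, abs=1e-8)

    def test_top_filter_beats_random_search(self, rng):
        A = rng.standard_normal((6, 6))
        B = rng.standard_normal((6, 6))
        cov = ef.ECSPCovariances(A @ A.T + 0.1 * np.eye(6), B @ B.T + 0.1 * np.eye(6))
        bank = ef.ecsp_filters(cov, 2)
        best = bank.eigenvalues[0]
        cand = rng.standard_normal((10_000, 6))
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        quots = np.einsum("ni,ij,nj->n", cand, cov.G1_shrunk, cand) / np.einsum(
            "ni,ij,nj->n", cand, cov.G2_shrunk, cand
        )
        assert best >= quots.max() - 1e-9

    def test_overfull_bank_duplicates_spectrum_ends(self, rng):
        A = rng.standard_normal((4, 4))
        cov = ef.ECSPCovariances(A @ A.T + 0.1 * np.eye(4), np.eye(4))
        bank = ef.ecsp_filters(cov, 6)
        assert bank.filters.shape == (6, 4)
        assert (np.diff(bank.eigenvalues) <= 1e-12).all()

    def test_unit_norm_rows(self, fitted_bank):
        np.testing.assert_allclose(np.linalg.norm(fitted_bank.filters, axis=1), 1.0)


class TestECSPFeatures:
    def test_zero_trial(self, rng):
        bank = ef.SpatialFilterBank(np.eye(3), np.array([3.0, 2.0, 1.0]))
        z = np.zeros((3, 50))
        np.testing.assert_allclose(ef.ecsp_features(z, bank, "mean_power"), 0.0)
        np.testing.assert_allclose(ef.ecsp_features(z, bank, "literal_mean"), 0.0)

    def test_hand_computed_projection(self):
        bank = ef.SpatialFilterBank(
            np.array([[1.0, 0.0], [0.6, 0.8]]), np.array([2.0, 1.0])
        )
        trial = np.array([[1.0, 2.0], [3.0, 4.0]])
        proj = bank.filters @ trial
        np.testing.assert_allclose(
            ef.ecsp_features(trial, bank, "mean_power"), (proj**2).mean(axis=1), atol=1e-10
        )
        np.testing.assert_allclose(
            ef.ecsp_features(trial, bank, "literal_mean"), proj.mean(axis=1), atol=1e-10
        )

    def test_mean_power_nonnegative(self, rng):
        bank = ef.SpatialFilterBank(np.eye(4), np.array([4.0, 3.0, 2.0, 1.0]))
        assert (ef.ecsp_features(rng.standard_normal((4, 64)), bank) >= 0).all()

    def test_dimension_mismatch_rejected(self):
        bank = ef.SpatialFilterBank(np.eye(3), np.array([3.0, 2.0, 1.0]))
        with pytest.raises(ValueError):
            ef.ecsp_features(np.zeros((4, 10)), bank)

    def test_top_filter_separates_variance_classes(self, rng):
        # class 1 has high variance on channel 0, class 0 on channel 3
        trials, labels = [], []
        for i in range(60):
            lab = i % 2
            scale = np.ones((4, 1))
            scale[0 if lab else 3] = 4.0
            trials.append(scale * rng.standard_normal((4, 256)))
            labels.append(lab)
        labels = np.array(labels)
        cov = ef.ecsp_covariances(trials, labels, ef.ECSPParams(weight_mode="scalar", fc=5, delta_f=100))
        bank = ef.ecsp_filters(cov, 2)
        feats = np.array([ef.ecsp_features(t, bank)[0] for t in trials])
        assert roc_auc_score(labels, feats) > 0.9


class TestFeatureVector:
    def test_canonical_252_layout(self, small_dataset, fitted_bank):
        v = ef.eeg_feature_vector(small_dataset[0], fitted_bank)
        assert v.shape == (252,)
        assert np.isfinite(v).all()
        assert len(ef.feature_names(22, 32)) == 252

    def test_18_channel_variant(self):
        from seizpipe import synthgen

        recs = synthgen.generate_eeg_dataset(12, 18, 256, 4, seed=3, n_subjects=10)
        bank = ef.fit_ecsp(recs)
        assert ef.eeg_feature_vector(recs[0], bank).shape == (212,)

    def test_channel_permutation_permutes_within_blocks(self, small_dataset, fitted_bank):
        rec = small_dataset[0]
        perm = np.arange(rec.n_channels)[::-1]
        rec_p = EEGRecord(rec.data[perm], rec.fs, rec.label, rec.subject_id)
        v = ef.eeg_feature_vector(rec, fitted_bank, rest_reference=rec.data)
        bank_p = ef.SpatialFilterBank(fitted_bank.filters[:, perm], fitted_bank.eigenvalues)
        v_p = ef.eeg_feature_vector(rec_p, bank_p, rest_reference=rec_p.data)
        spectral = v[:110].reshape(22, 5)
        spectral_p = v_p[:110].reshape(22, 5)
        np.testing.assert_allclose(spectral_p, spectral[perm], atol=1e-12)
        np.testing.assert_allclose(v_p[220:], v[220:], atol=1e-10)
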
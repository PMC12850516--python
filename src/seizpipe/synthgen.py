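"""Synthetic EEG segments, brain phantoms, and noise injection.

The generators emulate the statistical structure the downstream pipeline
assumes: balanced two-class EEG segments (1/f background vs. rhythmic
high-amplitude 3-7 Hz ictal-like oscillation) recorded from a cohort of
subjects, and smooth ellipsoidal brain phantoms with optional lesion-like
intensity blobs.  Every generator is a pure function of its arguments,
including the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "EEGRecord",
    "BrainImage",
    "NoiseSpec",
    "generate_eeg_dataset",
    "generate_brain_phantom",
    "add_noise",
    "save_eeg_dataset",
    "load_eeg_dataset",
]

DEFAULT_FS = 256.0
DEFAULT_DURATION_S = 8.0
#: cohort sizes mirror the two study populations the pipeline targets:
#: 24 pediatric scalp-EEG participants and 52 EEG-fMRI participants.
DEFAULT_EEG_SUBJECTS = 24
DEFAULT_PHANTOM_SUBJECTS = 52


@dataclass
class EEGRecord:
    """A multichannel EEG segment (channels x samples, microvolt scale)."""

    data: np.ndarray
    fs: float
    label: int
    subject_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise ValueError("EEG data must be a channels x samples matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data must be finite")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (healthy) or 1 (seizure)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class BrainImage:
    """A nonnegative 2-D or 3-D intensity grid with label and subject id."""

    data: np.ndarray
    label: int
    subject_id: str
    lesion_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError("brain image must be 2-D or 3-D")
        if any(s < 8 for s in self.data.shape):
            raise ValueError("each image dimension must be >= 8")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("image intensities must be finite and >= 0")


@dataclass
class NoiseSpec:
    """Noise model: additive Gaussian, salt-and-pepper impulses, or both."""

    model: Literal["gaussian", "impulse", "mixed"] = "gaussian"
    gaussian_sd: float = 0.1
    impulse_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("gaussian", "impulse", "mixed"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")
        if not 0.0 <= self.impulse_prob <= 1.0:
            raise ValueError("impulse_prob must lie in [0, 1]")
        if self.model == "mixed" and not (self.gaussian_sd > 0 and self.impulse_prob > 0):
            raise ValueError("mixed noise requires gaussian_sd > 0 and impulse_prob > 0")


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping of white Gaussian noise."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz] / freqs[nz][0])
    pink = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    pink /= pink.std(axis=1, keepdims=True) + 1e-12
    return pink


def _background_segment(
    rng: np.random.Generator, n_channels: int, fs: float, n_samples: int
) -> np.ndarray:
    """Interictal-like background: pink noise plus low-amplitude 10 Hz alpha."""
    t = np.arange(n_samples) / fs
    seg = 10.0 * _pink_noise(rng, n_channels, n_samples)
    phase = rng.uniform(0, 2 * np.pi, size=(n_channels, 1))
    alpha_amp = rng.uniform(1.5, 3.0, size=(n_channels, 1))
    seg += alpha_amp * np.sin(2 * np.pi * 10.0 * t[None, :] + phase)
    return seg


def _seizure_segment(
    rng: np.random.Generator, n_channels: int, fs: float, n_samples: int
) -> np.ndarray:
    """Ictal-like segment: rhythmic 3-7 Hz oscillation with harmonics and an
    amplitude envelope covering at least half of the segment, riding on the
    usual background.  Amplitude >= 3x the background RMS."""
    seg = _background_segment(rng, n_channels, fs, n_samples)
    bg_rms = np.sqrt(np.mean(seg**2))
    t = np.arange(n_samples) / fs
    duration_s = n_samples / fs
    f0 = rng.uniform(3.0, 7.0)
    # onset uniform in the first half so the burst spans >= 50 % of the segment
    onset = rng.uniform(0.0, 0.5 * duration_s)
    envelope = np.clip((t - onset) / 0.5, 0.0, 1.0)  # 0.5 s ramp-up
    phase = rng.uniform(0, 2 * np.pi, size=(n_channels, 1))
    wave = np.sin(2 * np.pi * f0 * t[None, :] + phase)
    wave += 0.4 * np.sin(2 * np.pi * 2 * f0 * t[None, :] + 2 * phase)
    wave += 0.2 * np.sin(2 * np.pi * 3 * f0 * t[None, :] + 3 * phase)
    amp = 3.5 * bg_rms * rng.uniform(1.0, 1.4, size=(n_channels, 1))
    seg += amp * envelope[None, :] * wave
    return seg


def generate_eeg_dataset(
    n_samples: int = 2500,
    n_channels: int = 22,
    fs: float = DEFAULT_FS,
    duration_s: float = DEFAULT_DURATION_S,
    seed: int = 0,
    n_subjects: int = DEFAULT_EEG_SUBJECTS,
) -> list[EEGRecord]:
    """Generate a balanced two-class EEG dataset.

    Half the records are interictal-like background (label 0), half contain a
    rhythmic 3-7 Hz seizure-like oscillation (label 1).  Records are
    partitioned across ``n_subjects`` subjects, each contributing both
    classes, so subject-independent splits are well defined.
    """
    if n_samples <= 0 or n_samples % 2 != 0:
        raise ValueError(
            f"n_samples must be a positive even count for class balance, got {n_samples}"
        )
    if n_channels < 2:
        raise ValueError(f"n_channels must be >= 2, got {n_channels}")
    n_pts = fs * duration_s
    if abs(n_pts - round(n_pts)) > 1e-9:
        raise ValueError("fs * duration_s must be an integral sample count")
    n_pts = int(round(n_pts))
    if n_subjects < 10:
        raise ValueError("need >= 10 subjects for subject-independent evaluation")

    rng = np.random.default_rng(seed)
    half = n_samples // 2
    records: list[EEGRecord] = []
    for label, n_label in ((0, half), (1, half)):
        for i in range(n_label):
            subject = f"sub-{i % n_subjects:02d}"
            gen = _seizure_segment if label else _background_segment
            data = gen(rng, n_channels, fs, n_pts)
            records.append(EEGRecord(data=data, fs=fs, label=label, subject_id=subject))
    return records


def generate_brain_phantom(
    shape: Sequence[int] = (32, 32),
    lesion: bool = False,
    seed: int = 0,
    subject_id: str = "sub-00",
) -> BrainImage:
    """Generate a smooth ellipsoidal brain phantom with intensities in [0, 1].

    With ``lesion=True`` a localized Gaussian blob raises the mean intensity
    inside a recorded mask (stored on the returned image), mimicking a
    lesion-like activation focus.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) not in (2, 3) or any(s < 8 for s in shape):
        raise ValueError(f"phantom shape must be 2-D/3-D with every dim >= 8, got {shape}")
    rng = np.random.default_rng(seed)

    grids = np.meshgrid(*[np.linspace(-1, 1, s) for s in shape], indexing="ij")
    semi_axes = rng.uniform(0.65, 0.85, size=len(shape))
    r2 = sum((g / a) ** 2 for g, a in zip(grids, semi_axes))
    # smooth ellipsoid with a soft edge and gentle internal texture
    img = 0.8 / (1.0 + np.exp((r2 - 1.0) / 0.08))
    texture = sum(
        0.05 * np.sin(np.pi * rng.uniform(1.5, 3.5) * g + rng.uniform(0, 2 * np.pi))
        for g in grids
    )
    img = img * (1.0 + texture)

    img = img / (np.abs(img).max() + 1e-12) * 0.75

    mask = None
    if lesion:
        center = rng.uniform(-0.4, 0.4, size=len(shape))
        width = rng.uniform(0.12, 0.2)
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        blob = 0.3 * np.exp(-d2 / (2 * width**2))
        img = img + blob
        mask = d2 <= (2 * width) ** 2

    img = np.clip(img, 0.0, 1.0)
    return BrainImage(data=img, label=int(lesion), subject_id=subject_id, lesion_mask=mask)


def generate_phantom_dataset(
    n_samples: int = 2500,
    shape: Sequence[int] = (32, 32),
    seed: int = 0,
    n_subjects: int = DEFAULT_PHANTOM_SUBJECTS,
) -> list[BrainImage]:
    """Balanced lesion / no-lesion phantom cohort across ``n_subjects``."""
    if n_samples <= 0 or n_samples % 2 != 0:
        raise ValueError("n_samples must be a positive even count")
    rng = np.random.default_rng(seed)
    half = n_samples // 2
    images: list[BrainImage] = []
    for label, n_label in ((0, half), (1, half)):
        for i in range(n_label):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            images.append(
                generate_brain_phantom(
                    shape=shape,
                    lesion=bool(label),
                    seed=sub_seed,
                    subject_id=f"sub-{i % n_subjects:02d}",
                )
            )
    return images


def add_noise(
    x: EEGRecord | BrainImage | np.ndarray, spec: NoiseSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(clean, noisy)`` for a record, image or bare array.

    Gaussian noise is i.i.d. additive with sd ``gaussian_sd``; impulse noise
    replaces a fraction ``impulse_prob`` of entries with the extremes of the
    clean data range (salt and pepper); ``mixed`` applies both.
    """
    if isinstance(x, EEGRecord) or isinstance(x, BrainImage):
        clean = x.data
    else:
        clean = np.asarray(x, dtype=float)
    rng = np.random.default_rng(spec.seed)
    noisy = clean.copy()
    if spec.model in ("gaussian", "mixed") and spec.gaussian_sd > 0:
        noisy = noisy + rng.normal(0.0, spec.gaussian_sd, size=clean.shape)
    if spec.model in ("impulse", "mixed") and spec.impulse_prob > 0:
        lo, hi = float(clean.min()), float(clean.max())
        hits = rng.random(clean.shape) < spec.impulse_prob
        salt = rng.random(clean.shape) < 0.5
        noisy = np.where(hits & salt, hi, noisy)
        noisy = np.where(hits & ~salt, lo, noisy)
    return clean, noisy


def save_eeg_dataset(records: Sequence[EEGRecord], directory: str | Path) -> None:
    """Serialize a dataset as ``signal_samples.npy`` / ``is_sz.npy`` plus a
    JSON sidecar holding subject ids and the sampling rate."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = np.stack([r.data for r in records])
    labels = np.array([r.label for r in records], dtype=np.int64)
    np.save(directory / "signal_samples.npy", data)
    np.save(directory / "is_sz.npy", labels)
    sidecar = {
        "fs": records[0].fs,
        "subject_ids": [r.subject_id for r in records],
    }
    (directory / "dataset.json").write_text(json.dumps(sidecar))


def load_eeg_dataset(directory: str | Path) -> list[EEGRecord]:
    directory = Path(directory)
    data = np.load(directory / "signal_samples.npy")
    labels = np.load(directory / "is_sz.npy")
    sidecar = json.loads((directory / "dataset.json").read_text())
    return [
        EEGRecord(data=d, fs=float(sidecar["fs"]), label=int(l), subject_id=s)
        for d, l, s in zip(data, labels, sidecar["subject_ids"])
    ]
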
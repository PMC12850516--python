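"""EEG descriptors: Welch band powers, temporal statistics, spectral
roll-off, and an enhanced common spatial pattern (E-CSP) chain.

The canonical per-record feature vector concatenates, in electrode-major
order, five band powers per channel, five temporal descriptors per channel,
and ``n_filters`` spatially filtered power features, giving 10*C + n_filters
values (252 for the default 22-channel / 32-filter configuration).

E-CSP departs from plain CSP in three ways: trials are passed through a
normalize -> softsign -> swish activation chain referenced to resting-state
statistics, class covariances are shrunk toward the identity, and trials are
frequency weighted around a configurable center band before covariance
estimation.  Filters come from the generalized symmetric eigenproblem
G1' w = lambda G2' w, the form that extremizes the between-class variance
ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal

from .synthgen import EEGRecord

__all__ = [
    "BandSpec",
    "ECSPParams",
    "ECSPCovariances",
    "SpatialFilterBank",
    "band_powers",
    "temporal_descriptors",
    "spectral_rolloff",
    "ecsp_activate",
    "frequency_weight",
    "ecsp_covariances",
    "ecsp_filters",
    "ecsp_features",
    "eeg_feature_vector",
    "fit_ecsp",
    "feature_matrix",
    "TEMPORAL_NAMES",
]

TEMPORAL_NAMES = (
    "hjorth_activity",
    "hjorth_mobility",
    "hjorth_complexity",
    "line_length",
    "zero_crossing_rate",
)


@dataclass
class BandSpec:
    """Named frequency bands with [low, high) Hz edges."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "delta": (0.5, 4.0),
            "theta": (4.0, 8.0),
            "alpha": (8.0, 13.0),
            "beta": (13.0, 30.0),
            "gamma": (30.0, 80.0),
        }
    )

    def __post_init__(self) -> None:
        edges = list(self.bands.values())
        for (lo, hi) in edges:
            if not 0 < lo < hi:
                raise ValueError(f"band edges must satisfy 0 < low < high, got ({lo}, {hi})")
        for (_, hi), (lo2, _) in zip(edges, edges[1:]):
            if lo2 < hi:
                raise ValueError("bands must be ascending and non-overlapping")

    @property
    def names(self) -> list[str]:
        return list(self.bands)


@dataclass
class ECSPParams:
    gamma1: float = 0.1
    gamma2: float = 0.1
    fc: float = 5.0
    delta_f: float = 4.0
    n_filters: int = 32
    feature_mode: str = "mean_power"
    weight_mode: str = "spectral"

    def __post_init__(self) -> None:
        for g in (self.gamma1, self.gamma2):
            if not 0.0 <= g <= 1.0:
                raise ValueError("shrinkage parameters must lie in [0, 1]")
        if self.delta_f <= 0:
            raise ValueError("delta_f must be > 0")
        if self.feature_mode not in ("mean_power", "literal_mean"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")
        if self.weight_mode not in ("spectral", "scalar"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")


@dataclass
class ECSPCovariances:
    """Shrunk class covariance matrices (task = seizure, rest = background)."""

    G1_shrunk: np.ndarray
    G2_shrunk: np.ndarray

    def __post_init__(self) -> None:
        for G in (self.G1_shrunk, self.G2_shrunk):
            if not np.allclose(G, G.T, atol=1e-10):
                raise ValueError("covariance must be symmetric")
            if np.linalg.eigvalsh(G).min() < -1e-8:
                raise ValueError("covariance must be positive semi-definite")


@dataclass
class SpatialFilterBank:
    """Unit-norm spatial filters (rows) with descending eigenvalues."""

    filters: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        self.filters = np.asarray(self.filters, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]


# ---------------------------------------------------------------------------
# spectral and temporal descriptors


def _welch(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with 2-s Hann segments and 50 % overlap."""
    nperseg = min(int(2 * fs), x.shape[-1])
    return signal.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)


def band_powers(x: EEGRecord, bands: BandSpec | None = None) -> np.ndarray:
    """Per-channel absolute band powers (channels x bands) from Welch PSD.

    Bands that extend past Nyquist are integrated up to Nyquist; bands that
    lie entirely above Nyquist are reported as zero with a warning.
    """
    bands = bands or BandSpec()
    freqs, psd = _welch(x.data, x.fs)
    nyq = x.fs / 2.0
    out = np.zeros((x.n_channels, len(bands.bands)))
    for j, (name, (lo, hi)) in enumerate(bands.bands.items()):
        if lo >= nyq:
            warnings.warn(f"band {name!r} lies above Nyquist ({nyq} Hz); reported as 0")
            continue
        sel = (freqs >= lo) & (freqs < min(hi, nyq))
        if sel.any():
            df = freqs[1] - freqs[0]
            out[:, j] = psd[:, sel].sum(axis=1) * df  # rectangle rule over [lo, hi)
    return out


def temporal_descriptors(x: EEGRecord) -> np.ndarray:
    """Per-channel Hjorth activity/mobility/complexity, line length and
    zero-crossing rate (channels x 5).

    Activity is the signal variance; mobility sqrt(var(dx)/var(x));
    complexity mobility(dx)/mobility(x); line length the summed absolute
    successive difference; ZCR the sign-change count per second.  Degenerate
    (constant) channels report 0 for the guarded ratios.
    """
    data = x.data
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples per channel")
    var = data.var(axis=1)
    d1 = np.diff(data, axis=1)
    d2 = np.diff(d1, axis=1)
    var1 = d1.var(axis=1)
    var2 = d2.var(axis=1)

    def safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

    mobility = np.sqrt(safe_ratio(var1, var))
    mob_d = np.sqrt(safe_ratio(var2, var1))
    complexity = safe_ratio(mob_d, mobility)

    line_length = np.abs(d1).sum(axis=1)
    signs = np.sign(data)
    # treat exact zeros as positive so a constant-zero channel has ZCR 0
    signs[signs == 0] = 1
    zcr = (np.diff(signs, axis=1) != 0).sum(axis=1) / x.duration_s
    return np.column_stack([var, mobility, complexity, line_length, zcr])


def spectral_rolloff(x: np.ndarray, fs: float, pct: float = 0.85) -> float:
    """Smallest frequency below which ``pct`` of the total Welch power lies.

    A zero (all-silent) channel rolls off at 0 Hz.
    """
    if not 0.0 < pct < 1.0:
        raise ValueError("pct must lie in (0, 1)")
    x = np.asarray(x, dtype=float)
    freqs, psd = _welch(x, fs)
    total = psd.sum()
    if total <= 0:
        warnings.warn("zero signal: spectral roll-off reported as 0 Hz")
        return 0.0
    cum = np.cumsum(psd)
    idx = int(np.searchsorted(cum, pct * total))
    return float(freqs[min(idx, len(freqs) - 1)])


# ---------------------------------------------------------------------------
# E-CSP


def ecsp_activate(task: np.ndarray, rest: np.ndarray) -> np.ndarray:
    """Activation chain: standardize against resting-state statistics, then
    softsign, then swish.

    z_hat = (Z - mu_rest) / sd_rest; softsign(z) = z / (1 + |z|);
    swish(u) = u * sigmoid(u).  The softsign stage bounds values in (-1, 1),
    so the output lies in roughly (-0.27, 1).
    """
    task = np.asarray(task, dtype=float)
    rest = np.asarray(rest, dtype=float)
    mu, sd = rest.mean(), rest.std()
    if sd <= 0:
        raise ValueError("resting-state reference is constant (sd = 0); cannot standardize")
    z = (task - mu) / sd
    s = z / (1.0 + np.abs(z))
    return s / (1.0 + np.exp(-s))


def frequency_weight(f: np.ndarray | float, fc: float, delta_f: float) -> np.ndarray | float:
    """Rational band emphasis w(f) = 1 / (1 + 4((f - fc)/delta_f)^2).

    Equals 1 at fc, 0.5 at fc +/- delta_f/2 and 0.2 at fc +/- delta_f.
    """
    if delta_f <= 0:
        raise ValueError("delta_f must be > 0")
    f = np.asarray(f, dtype=float)
    w = 1.0 / (1.0 + 4.0 * ((f - fc) / delta_f) ** 2)
    return float(w) if w.ndim == 0 else w


def _spectral_weight_trial(trial: np.ndarray, fs: float, fc: float, delta_f: float) -> np.ndarray:
    """Band-limit a trial to [fc - delta_f, fc + delta_f] and weight its PSD
    by the frequency-weight curve (amplitude scaled by sqrt(w))."""
    n = trial.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    w = np.sqrt(frequency_weight(freqs, fc, delta_f))
    w = np.where((freqs >= max(fc - delta_f, 0.0)) & (freqs <= fc + delta_f), w, 0.0)
    return np.fft.irfft(np.fft.rfft(trial, axis=-1) * w[None, :], n=n, axis=-1)


def _dominant_frequency(trial: np.ndarray, fs: float) -> float:
    freqs = np.fft.rfftfreq(trial.shape[-1], d=1.0 / fs)
    spec = (np.abs(np.fft.rfft(trial, axis=-1)) ** 2).mean(axis=0)
    return float(freqs[int(np.argmax(spec))])


def ecsp_covariances(
    trials: list[np.ndarray],
    labels: np.ndarray,
    params: ECSPParams = ECSPParams(),
    fs: float = 256.0,
) -> ECSPCovariances:
    """Frequency-weighted, shrunk class covariances.

    ``spectral`` weighting (default) band-limits each trial around fc and
    weights the spectrum; ``scalar`` weights each trial's covariance by the
    frequency-weight curve evaluated at its dominant frequency.  Shrinkage:
    G' = (1 - gamma) G + gamma I.
    """
    labels = np.asarray(labels)
    if not (np.any(labels == 1) and np.any(labels == 0)):
        raise ValueError("need at least one trial per class")

    covs = {0: [], 1: []}
    for trial, lab in zip(trials, labels):
        trial = np.asarray(trial, dtype=float)
        if params.weight_mode == "spectral":
            t = _spectral_weight_trial(trial, fs, params.fc, params.delta_f)
            cov = t @ t.T / t.shape[1]
        else:
            w = frequency_weight(_dominant_frequency(trial, fs), params.fc, params.delta_f)
            cov = w * (trial @ trial.T) / trial.shape[1]
        covs[int(lab)].append(cov)

    G1 = np.mean(covs[1], axis=0)  # task (seizure)
    G2 = np.mean(covs[0], axis=0)  # rest (background)
    J = np.eye(G1.shape[0])
    return ECSPCovariances(
        G1_shrunk=(1.0 - params.gamma1) * G1 + params.gamma1 * J,
        G2_shrunk=(1.0 - params.gamma2) * G2 + params.gamma2 * J,
    )


def ecsp_filters(cov: ECSPCovariances, n_filters: int = 32) -> SpatialFilterBank:
    """Spatial filters from the generalized eigenproblem G1' w = lambda G2' w.

    Filters are taken alternately from both ends of the eigenvalue spectrum
    (largest variance ratio for the task class and for the rest class), then
    ordered by descending eigenvalue; rows are unit-norm.  When the
    requested bank is larger than the channel count (the canonical 32-filter
    bank over 22 channels), the two half-banks overlap in the middle of the
    spectrum and those eigenvectors appear twice.  A singular G2' is ridged
    with a small epsilon and a warning.
    """
    G1, G2 = cov.G1_shrunk, cov.G2_shrunk
    C = G1.shape[0]
    if n_filters > 2 * C:
        raise ValueError(f"n_filters={n_filters} exceeds twice the channel count {C}")
    try:
        evals, evecs = linalg.eigh(G1, G2)
    except linalg.LinAlgError:
        warnings.warn("singular rest covariance; adding ridge 1e-8 I")
        evals, evecs = linalg.eigh(G1, G2 + 1e-8 * np.eye(C))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    n_top = (n_filters + 1) // 2
    n_bot = n_filters // 2
    # ends overlap (duplicate indices) only when n_filters > C
    take = sorted(list(range(n_top)) + list(range(C - n_bot, C)))
    filt = evecs[:, take].T
    filt /= np.linalg.norm(filt, axis=1, keepdims=True)
    return SpatialFilterBank(filters=filt, eigenvalues=evals[take])


def ecsp_features(
    trial: np.ndarray, bank: SpatialFilterBank, mode: str = "mean_power"
) -> np.ndarray:
    """Per-filter summary of the spatially projected trial.

    ``mean_power`` (default) is the mean squared projected sample — the
    variance feature classic CSP uses; ``literal_mean`` is the arithmetic
    mean of the projected signal.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.shape[0] != bank.filters.shape[1]:
        raise ValueError(
            f"trial has {trial.shape[0]} channels, bank expects {bank.filters.shape[1]}"
        )
    proj = bank.filters @ trial
    if mode == "mean_power":
        return (proj**2).mean(axis=1)
    if mode == "literal_mean":
        return proj.mean(axis=1)
    raise ValueError(f"unknown mode {mode!r}")


def fit_ecsp(
    records: list[EEGRecord], params: ECSPParams = ECSPParams()
) -> SpatialFilterBank:
    """Fit an E-CSP filter bank from labelled records.

    Seizure records are the task class; background records double as the
    resting-state reference for the activation chain.
    """
    rest = np.concatenate([r.data for r in records if r.label == 0], axis=1)
    trials = [ecsp_activate(r.data, rest) for r in records]
    labels = np.array([r.label for r in records])
    cov = ecsp_covariances(trials, labels, params, fs=records[0].fs)
    return ecsp_filters(cov, params.n_filters)


def ecsp_objective(cov: ECSPCovariances, w: np.ndarray) -> float:
    """Diagnostic Rayleigh quotient w'G1'w / w'G2'w."""
    w = np.asarray(w, dtype=float)
    return float((w @ cov.G1_shrunk @ w) / (w @ cov.G2_shrunk @ w))


# ---------------------------------------------------------------------------
# assembled vector


def eeg_feature_vector(
    x: EEGRecord,
    bank: SpatialFilterBank,
    bands: BandSpec | None = None,
    feature_mode: str = "mean_power",
    rest_reference: np.ndarray | None = None,
) -> np.ndarray:
    """Concatenated [band powers | temporal descriptors | E-CSP] vector.

    Blocks are electrode-major (channel 0's five bands, channel 1's five
    bands, ...), so the length is 10*C + n_filters — 252 for 22 channels and
    32 filters.  ``rest_reference`` supplies the resting-state statistics for
    the E-CSP activation; by default the record itself is used.
    """
    bands = bands or BandSpec()
    spectral = band_powers(x, bands).ravel()  # electrode-major
    temporal = temporal_descriptors(x).ravel()
    ref = x.data if rest_reference is None else rest_reference
    activated = ecsp_activate(x.data, ref)
    spatial = ecsp_features(activated, bank, mode=feature_mode)
    return np.concatenate([spectral, temporal, spatial])


def feature_matrix(
    records: list[EEGRecord],
    bank: SpatialFilterBank,
    bands: BandSpec | None = None,
    feature_mode: str = "mean_power",
    rest_reference: np.ndarray | None = None,
) -> np.ndarray:
    return np.stack(
        [
            eeg_feature_vector(r, bank, bands, feature_mode, rest_reference)
            for r in records
        ]
    )


def feature_names(n_channels: int, n_filters: int, bands: BandSpec | None = None) -> list[str]:
    """Column names matching the assembled vector layout."""
    bands = bands or BandSpec()
    names = [f"ch{c:02d}_{b}_power" for c in range(n_channels) for b in bands.names]
    names += [f"ch{c:02d}_{t}" for c in range(n_channels) for t in TEMPORAL_NAMES]
    names += [f"ecsp_{i:02d}" for i in range(n_filters)]
    return names
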
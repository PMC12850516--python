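"""Soft-voting hybrid parallel convolutional / ghost-feature classifier.

Two heterogeneous learners score each sample:

* **IAPCNet** — a dual-branch network: a 1-D convolutional branch over the
  EEG feature vector and a 2-D branch over the image feature vector
  (reshaped to a map), each built from depthwise-separable convolutions, an
  updated batch normalization (UBN) whose per-channel gate mixes max and
  average pooling of a composite Softplus-tanh/GELU-ELU activation, a tanh
  nonlinearity, max pooling, and a spatial-perceptual attention block that
  re-weights the map along its height and width axes.
* **GhostNet** — a compact stack of ghost modules that synthesize most of
  their output channels with cheap depthwise transforms of a small set of
  intrinsic maps.

The convolutional stages are seed-initialized and frozen (random
convolutional features); only the dense softmax heads are trained, with
Adam on binary cross-entropy and early stopping on validation loss.  The
two probability outputs are fused by weighted soft voting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from . import _nn
from ._nn import MLPHead, softmax

__all__ = [
    "StGENParams",
    "UBNState",
    "IAPCNetConfig",
    "GhostNetConfig",
    "TrainConfig",
    "chaotic_map_sequence",
    "stge_activation",
    "mixed_pool",
    "attention_norm",
    "ubn_forward",
    "SPCIIAttention",
    "SPCIIAttention1D",
    "GhostModule",
    "IAPCNet",
    "GhostNetClassifier",
    "soft_vote",
    "train",
]


# ---------------------------------------------------------------------------
# elementary blocks


def chaotic_map_sequence(x0: float, q: float, n: int) -> np.ndarray:
    """Iterates of the piecewise-linear chaotic map.

    x_{k+1} = x_k / q if x_k < q else (1 - x_k) / (1 - q); all iterates stay
    in [0, 1].  Used to draw the fixed scaling factors of the composite
    activation at initialization.
    """
    if not (0.0 < x0 < 1.0 and 0.0 < q < 1.0):
        raise ValueError("x0 and q must lie in (0, 1)")
    out = np.empty(n)
    x = x0
    for i in range(n):
        x = x / q if x < q else (1.0 - x) / (1.0 - q)
        out[i] = x
    return out


@dataclass
class StGENParams:
    """Composite-activation / mixed-pooling parameters.

    varpi and vartheta scale the ELU and GELU parts of the negative branch;
    chi mixes max and average pooling; q, x0 parameterize the chaotic map
    that draws varpi and vartheta at initialization.
    """

    varpi: float = 0.5
    vartheta: float = 0.5
    chi: float = 0.5
    q: float = 0.37
    x0: float = 0.21

    def __post_init__(self) -> None:
        for name in ("varpi", "vartheta", "q", "x0"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0.0 <= self.chi <= 1.0:
            raise ValueError("chi must lie in [0, 1]")

    @classmethod
    def from_chaotic_map(cls, x0: float = 0.21, q: float = 0.37, chi: float = 0.5) -> "StGENParams":
        """Draw varpi and vartheta as consecutive chaotic-map iterates."""
        it = chaotic_map_sequence(x0, q, 8)
        # keep strictly inside (0,1): skip iterates that hit the boundary
        vals = [v for v in it if 0.0 < v < 1.0]
        return cls(varpi=vals[0], vartheta=vals[1], chi=chi, q=q, x0=x0)


def stge_activation(
    x: np.ndarray | float, varpi: float = 0.5, vartheta: float = 0.5
) -> np.ndarray | float:
    """Composite activation: x*tanh(softplus(x)) for x >= 0 (the Mish form),
    varpi*ELU(x) + vartheta*GELU(x) for x < 0.  Continuous at 0."""
    x = np.asarray(x, dtype=float)
    pos = x * np.tanh(np.logaddexp(0.0, x))
    elu = np.expm1(np.minimum(x, 0.0))
    gelu = 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))
    neg = varpi * elu + vartheta * gelu
    out = np.where(x >= 0, pos, neg)
    return float(out) if out.ndim == 0 else out


def mixed_pool(s: np.ndarray, chi: float = 0.5) -> float:
    """chi * max(s) + (1 - chi) * mean(s) over a nonempty region."""
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("mixed_pool needs a nonempty region")
    return float(chi * s.max() + (1.0 - chi) * s.mean())


def attention_norm(x: np.ndarray, w1: float = 1.0, b: float = 0.0) -> np.ndarray:
    """Attention-modulated standardization over the channel axis:
    ((x - mu)/sigma) * (1 + softmax(w1*x + b)).  A constant input has no
    spread to standardize and maps to zeros."""
    x = np.asarray(x, dtype=float)
    mu, sd = x.mean(), x.std()
    if sd <= 0:
        return np.zeros_like(x)
    return ((x - mu) / sd) * (1.0 + softmax(w1 * x + b))


@dataclass
class UBNState:
    """Updated-batch-normalization state for one layer.

    In training mode statistics come from the batch (and are stored as
    running statistics); in inference mode the stored statistics are used.
    The gate Q is the mixed-pooled composite activation of the standardized
    map, per channel per sample (``q_mode='stgen'``), or identically 1
    (``q_mode='identity'``, plain batch normalization).
    """

    eps: float = 1e-5
    scale: float = 1.0
    shift: float = 0.0
    w1: float = 1.0
    b: float = 0.0
    q_mode: str = "stgen"
    stgen: StGENParams = field(default_factory=StGENParams)
    running_mean: np.ndarray | None = None
    running_var: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.q_mode not in ("stgen", "identity"):
            raise ValueError(f"unknown q_mode {self.q_mode!r}")


def _channel_softmax_norm(z: np.ndarray, w1: float, b: float) -> np.ndarray:
    """Eq.-style attention normalization applied along the channel axis
    (axis 1) at every (sample, position)."""
    mu = z.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    std = np.where(sd > 0, (z - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return std * (1.0 + softmax(w1 * z + b, axis=1))


def ubn_forward(
    batch: np.ndarray,
    state: UBNState,
    training: bool = True,
    return_standardized: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Updated batch normalization.

    ``batch`` is (N, C) or (N, C, *spatial).  The activation is standardized
    per channel, then multiplied by the gate Q: the composite activation
    f''(z) = stge(z) * attention_norm(z) is mixed-pooled over each sample's
    spatial extent, giving a per-(sample, channel) scalar gate.  With
    ``q_mode='identity'`` the layer is standard batch normalization.
    """
    x = np.asarray(batch, dtype=float)
    if x.ndim < 2:
        raise ValueError("batch must be at least (N, C)")
    axes = (0,) + tuple(range(2, x.ndim))
    if training:
        if x.shape[0] < 2:
            raise ValueError("training-mode normalization needs a batch of >= 2 samples")
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        state.running_mean, state.running_var = mean, var
    else:
        if state.running_mean is None or state.running_var is None:
            raise ValueError("inference mode requires stored running statistics")
        mean, var = state.running_mean, state.running_var
    shape = (1, -1) + (1,) * (x.ndim - 2)
    z = (x - mean.reshape(shape)) / np.sqrt(var.reshape(shape) + state.eps)

    if state.q_mode == "identity":
        q = 1.0
    else:
        p = state.stgen
        f = stge_activation(z, p.varpi, p.vartheta)
        f2 = f * _channel_softmax_norm(z, state.w1, state.b)
        if x.ndim == 2:
            q = f2
        else:
            spatial = tuple(range(2, x.ndim))
            q_val = p.chi * f2.max(axis=spatial) + (1 - p.chi) * f2.mean(axis=spatial)
            q = q_val.reshape(q_val.shape + (1,) * (x.ndim - 2))
    out = z * q * state.scale + state.shift
    if return_standardized:
        return out, z
    return out


# ---------------------------------------------------------------------------
# attention and ghost blocks


def _instance_norm(x: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    mu = x.mean(axis=axes, keepdims=True)
    sd = x.std(axis=axes, keepdims=True)
    return np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)


class SPCIIAttention:
    """Spatial-perceptual attention over height and width of a (C, H, W) map.

    Each branch aggregates the map with average and max pooling along the
    complementary axis, stacks the two summaries as a 2-channel image,
    passes it through a seeded 3x3 convolution with normalization and a
    rectifier, aggregates again across the learned filters, applies a 1-D
    cross-interaction convolution (kernel 3) and a sigmoid, and yields an
    attention profile in (0, 1) over that axis.  The input is re-weighted by
    both profiles.  Biases are zero, so a zero map gets profiles of 0.5.
    """

    def __init__(self, channels: int, seed: int = 0, kernel: int = 3):
        n_filters = max(channels // 4, 4)
        rng = np.random.default_rng(seed)
        self.w_h = _nn.he_init(rng, (n_filters, 2, kernel, kernel), fan_in=2 * kernel**2)
        self.w_w = _nn.he_init(rng, (n_filters, 2, kernel, kernel), fan_in=2 * kernel**2)
        self.acci_h = _nn.he_init(rng, (1, 1, kernel), fan_in=kernel)
        self.acci_w = _nn.he_init(rng, (1, 1, kernel), fan_in=kernel)

    def _profile(self, x: np.ndarray, axis: int, w: np.ndarray, acci: np.ndarray) -> np.ndarray:
        # aggregate over the complementary spatial axis -> (N, C, A)
        ap = x.mean(axis=axis)
        mp = x.max(axis=axis)
        stacked = np.stack([ap, mp], axis=1)  # (N, 2, C, A)
        conv = _nn.conv2d(stacked, w)
        conv = np.maximum(_instance_norm(conv, axes=(2, 3)), 0.0)
        agg = conv.mean(axis=1) + conv.max(axis=1)  # (N, C, A)
        vec = agg.mean(axis=1)  # (N, A)
        out = _nn.conv1d(vec[:, None, :], acci)[:, 0, :]
        return 1.0 / (1.0 + np.exp(-out))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        single = x.ndim == 3
        if single:
            x = x[None]
        if x.shape[2] < 2 or x.shape[3] < 2:
            raise ValueError("attention needs spatial dims >= 2")
        p_h = self._profile(x, axis=3, w=self.w_h, acci=self.acci_h)  # (N, H)
        p_w = self._profile(x, axis=2, w=self.w_w, acci=self.acci_w)  # (N, W)
        out = x * p_h[:, None, :, None] * p_w[:, None, None, :]
        return out[0] if single else out

    def profiles(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if x.ndim == 3:
            x = x[None]
        return (
            self._profile(x, axis=3, w=self.w_h, acci=self.acci_h),
            self._profile(x, axis=2, w=self.w_w, acci=self.acci_w),
        )


class SPCIIAttention1D:
    """Length-axis half of the spatial attention, for (C, L) maps."""

    def __init__(self, channels: int, seed: int = 0, kernel: int = 3):
        n_filters = max(channels // 4, 4)
        rng = np.random.default_rng(seed)
        self.w = _nn.he_init(rng, (n_filters, 2, kernel), fan_in=2 * kernel)
        self.acci = _nn.he_init(rng, (1, 1, kernel), fan_in=kernel)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        single = x.ndim == 2
        if single:
            x = x[None]
        ap = x.mean(axis=1)  # (N, L)
        mp = x.max(axis=1)
        stacked = np.stack([ap, mp], axis=1)  # (N, 2, L)
        conv = _nn.conv1d(stacked, self.w)
        conv = np.maximum(_instance_norm(conv, axes=(2,)), 0.0)
        vec = conv.mean(axis=1) + conv.max(axis=1)  # (N, L)
        out = _nn.conv1d(vec[:, None, :], self.acci)[:, 0, :]
        p = 1.0 / (1.0 + np.exp(-out))
        out = x * p[:, None, :]
        return out[0] if single else out


@dataclass
class GhostNetConfig:
    ratio: int = 2
    stem_width: int = 16
    stage_widths: tuple[int, ...] = (32, 64)
    kernel: int = 3

    def __post_init__(self) -> None:
        if self.ratio < 2 or int(self.ratio) != self.ratio:
            raise ValueError("ghost ratio must be an integer >= 2")


class GhostModule:
    """Ghost convolution block: a primary convolution produces
    out_channels/ratio intrinsic maps; cheap depthwise transforms generate
    the remaining (ratio-1)/ratio of the channels."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        ratio: int = 2,
        kernel: int = 3,
        seed: int = 0,
        cheap_init: str = "random",
    ):
        if out_channels % ratio != 0:
            raise ValueError(f"out_channels={out_channels} not divisible by ratio={ratio}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.ratio = ratio
        self.kernel = kernel
        intrinsic = out_channels // ratio
        rng = np.random.default_rng(seed)
        self.w_primary = _nn.he_init(
            rng, (intrinsic, in_channels, kernel, kernel), fan_in=in_channels * kernel**2
        )
        n_ghost = intrinsic * (ratio - 1)
        if cheap_init == "identity":
            w = np.zeros((n_ghost, kernel, kernel))
            w[:, kernel // 2, kernel // 2] = 1.0
            self.w_cheap = w
        else:
            self.w_cheap = _nn.he_init(rng, (n_ghost, kernel, kernel), fan_in=kernel**2)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        single = x.ndim == 3
        if single:
            x = x[None]
        intrinsic = np.maximum(_nn.conv2d(x, self.w_primary), 0.0)
        reps = np.repeat(intrinsic, self.ratio - 1, axis=1)
        ghosts = _nn.depthwise_conv2d(reps, self.w_cheap)
        out = np.concatenate([intrinsic, ghosts], axis=1)
        return out[0] if single else out

    @property
    def param_count(self) -> int:
        return self.w_primary.size + self.w_cheap.size

    @staticmethod
    def dense_param_count(in_channels: int, out_channels: int, kernel: int = 3) -> int:
        return in_channels * out_channels * kernel * kernel


# ---------------------------------------------------------------------------
# classifiers


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("lr, batch_size and epochs must be positive")


@dataclass
class IAPCNetConfig:
    eeg_dim: int | None = 252
    fmri_dim: int | None = 384
    fmri_map_shape: tuple[int, int] = (16, 24)
    widths: tuple[int, int] = (32, 64)
    kernel: int = 3
    dense: tuple[int, ...] = (128, 64)
    dropout: float = 0.3
    chi: float = 0.5
    chaotic_x0: float = 0.21
    chaotic_q: float = 0.37
    q_mode: str = "stgen"
    use_attention: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eeg_dim is None and self.fmri_dim is None:
            raise ValueError("at least one modality branch must be enabled")
        if self.fmri_dim is not None:
            h, w = self.fmri_map_shape
            if h * w != self.fmri_dim:
                raise ValueError(
                    f"fmri_map_shape {self.fmri_map_shape} incompatible with dim {self.fmri_dim}"
                )


def _check_val_classes(y_val: np.ndarray) -> None:
    if len(np.unique(y_val)) < 2:
        raise ValueError("validation set must contain both classes")


class _FrozenEncoderClassifier:
    """Shared plumbing: frozen encoder -> standardized features -> MLP head."""

    head: MLPHead
    _feat_mean: np.ndarray
    _feat_sd: np.ndarray

    def encode(self, X, fit_stats: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _standardize(self, feats: np.ndarray, fit: bool) -> np.ndarray:
        if fit:
            self._feat_mean = feats.mean(axis=0)
            self._feat_sd = feats.std(axis=0) + 1e-8
        return (feats - self._feat_mean) / self._feat_sd

    def fit(self, X, y, X_val, y_val, config: TrainConfig = TrainConfig()):
        y = np.asarray(y, dtype=int)
        y_val = np.asarray(y_val, dtype=int)
        _check_val_classes(y_val)
        feats = self._standardize(self.encode(X, fit_stats=True), fit=True)
        feats_val = self._standardize(self.encode(X_val), fit=False)
        self.history = self.head.fit(
            feats,
            y,
            feats_val,
            y_val,
            lr=config.lr,
            batch_size=config.batch_size,
            epochs=config.epochs,
            patience=config.patience,
            seed=config.seed,
        )
        return self.history

    def predict_proba(self, X) -> np.ndarray:
        feats = self._standardize(self.encode(X), fit=False)
        return self.head.predict_proba(feats)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


class IAPCNet(_FrozenEncoderClassifier):
    """Dual-branch attention network over EEG and image feature vectors.

    The 1-D branch convolves the EEG feature vector; the 2-D branch
    convolves the image feature vector reshaped to a map.  Each branch runs
    two (depthwise-separable) convolution / UBN / tanh / max-pool stages and
    an attention block; flattened branch outputs are concatenated and
    classified by a trainable dense softmax head with dropout.
    """

    def __init__(self, config: IAPCNetConfig = IAPCNetConfig()):
        self.config = config
        c1, c2 = config.widths
        k = config.kernel
        rng = np.random.default_rng(config.seed)
        stgen = StGENParams.from_chaotic_map(config.chaotic_x0, config.chaotic_q, config.chi)

        def make_ubn():
            return UBNState(q_mode=config.q_mode, stgen=replace(stgen))

        if config.eeg_dim is not None:
            self.w1d_a = _nn.he_init(rng, (c1, 1, k), fan_in=k)
            self.w1d_dw = _nn.he_init(rng, (c1, k), fan_in=k)
            self.w1d_pw = _nn.he_init(rng, (c2, c1, 1), fan_in=c1)
            self.ubn1d = (make_ubn(), make_ubn())
            self.att1d = SPCIIAttention1D(c2, seed=config.seed + 1)
        if config.fmri_dim is not None:
            self.w2d_a = _nn.he_init(rng, (c1, 1, k, k), fan_in=k * k)
            self.w2d_dw = _nn.he_init(rng, (c1, k, k), fan_in=k * k)
            self.w2d_pw = _nn.he_init(rng, (c2, c1, 1, 1), fan_in=c1)
            self.ubn2d = (make_ubn(), make_ubn())
            self.att2d = SPCIIAttention(c2, seed=config.seed + 2)

        feat_dim = self._encoded_dim()
        self.head = MLPHead(
            feat_dim,
            hidden=config.dense,
            n_classes=2,
            dropout=config.dropout,
            seed=config.seed + 3,
        )

    def _encoded_dim(self) -> int:
        cfg = self.config
        c2 = cfg.widths[1]
        dim = 0
        if cfg.eeg_dim is not None:
            dim += c2 * (cfg.eeg_dim // 4)
        if cfg.fmri_dim is not None:
            h, w = cfg.fmri_map_shape
            dim += c2 * (h // 4) * (w // 4)
        return dim

    def _branch1d(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = x[:, None, :]  # (N, 1, L)
        h = _nn.conv1d(h, self.w1d_a)
        h = np.tanh(ubn_forward(h, self.ubn1d[0], training=training))
        h = _nn.maxpool1d(h)
        h = _nn.depthwise_conv1d(h, self.w1d_dw)
        h = _nn.conv1d(h, self.w1d_pw)
        h = np.tanh(ubn_forward(h, self.ubn1d[1], training=training))
        h = _nn.maxpool1d(h)
        if self.config.use_attention:
            h = self.att1d(h)
        return h.reshape(h.shape[0], -1)

    def _branch2d(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = x.reshape(x.shape[0], 1, *self.config.fmri_map_shape)
        h = _nn.conv2d(h, self.w2d_a)
        h = np.tanh(ubn_forward(h, self.ubn2d[0], training=training))
        h = _nn.maxpool2d(h)
        h = _nn.depthwise_conv2d(h, self.w2d_dw)
        h = _nn.conv2d(h, self.w2d_pw)
        h = np.tanh(ubn_forward(h, self.ubn2d[1], training=training))
        h = _nn.maxpool2d(h)
        if self.config.use_attention:
            h = self.att2d(h)
        return h.reshape(h.shape[0], -1)

    def encode(self, X, fit_stats: bool = False) -> np.ndarray:
        """X is (X_eeg, X_fmri); a disabled branch takes None."""
        x_eeg, x_fmri = X if isinstance(X, tuple) else (X, None)
        parts = []
        cfg = self.config
        if cfg.eeg_dim is not None:
            x_eeg = np.asarray(x_eeg, dtype=float)
            if x_eeg.shape[1] != cfg.eeg_dim:
                raise ValueError(f"expected EEG dim {cfg.eeg_dim}, got {x_eeg.shape[1]}")
            parts.append(self._branch1d(x_eeg, training=fit_stats))
        if cfg.fmri_dim is not None:
            x_fmri = np.asarray(x_fmri, dtype=float)
            if x_fmri.shape[1] != cfg.fmri_dim:
                raise ValueError(f"expected image dim {cfg.fmri_dim}, got {x_fmri.shape[1]}")
            parts.append(self._branch2d(x_fmri, training=fit_stats))
        return np.concatenate(parts, axis=1)


@dataclass
class GhostClassifierConfig:
    in_dim: int = 636
    map_shape: tuple[int, int] = (16, 40)
    ghost: GhostNetConfig = field(default_factory=GhostNetConfig)
    dense: tuple[int, ...] = (64,)
    dropout: float = 0.0
    chi: float = 0.5
    seed: int = 0


class GhostNetClassifier(_FrozenEncoderClassifier):
    """Compact ghost-module stack over the fused feature vector.

    The feature vector is zero-padded to a 2-D map, passed through a stem
    convolution and two ghost stages with max pooling, read out with
    per-channel mixed pooling (max/average blend), and classified by a
    trainable dense head.
    """

    def __init__(self, config: GhostClassifierConfig = GhostClassifierConfig()):
        self.config = config
        g = config.ghost
        h, w = config.map_shape
        if h * w < config.in_dim:
            raise ValueError("map_shape too small for in_dim")
        rng = np.random.default_rng(config.seed)
        k = g.kernel
        self.w_stem = _nn.he_init(rng, (g.stem_width, 1, k, k), fan_in=k * k)
        self.stages = []
        cin = g.stem_width
        for i, cout in enumerate(g.stage_widths):
            self.stages.append(
                GhostModule(cin, cout, ratio=g.ratio, kernel=k, seed=config.seed + 10 + i)
            )
            cin = cout
        self.head = MLPHead(
            2 * cin, hidden=config.dense, n_classes=2,
            dropout=config.dropout, seed=config.seed + 99,
        )

    def encode(self, X, fit_stats: bool = False) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.shape[1] != self.config.in_dim:
            raise ValueError(f"expected dim {self.config.in_dim}, got {x.shape[1]}")
        h, w = self.config.map_shape
        pad = h * w - x.shape[1]
        if pad:
            x = np.pad(x, ((0, 0), (0, pad)))
        maps = x.reshape(x.shape[0], 1, h, w)
        maps = np.maximum(_nn.conv2d(maps, self.w_stem), 0.0)
        maps = _nn.maxpool2d(maps)
        for stage in self.stages:
            maps = stage(maps)
            maps = _nn.maxpool2d(maps)
        flat = maps.reshape(maps.shape[0], maps.shape[1], -1)
        chi = self.config.chi
        pooled = chi * flat.max(axis=2) + (1 - chi) * flat.mean(axis=2)
        return np.concatenate([pooled, flat.std(axis=2)], axis=1)


# ---------------------------------------------------------------------------
# fusion and training


def soft_vote(
    scores: list[np.ndarray], psi: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted soft voting over per-classifier class probabilities.

    ``fused = sum_i psi_i * scores_i`` with psi >= 0 renormalized to sum 1;
    labels are the fused argmax, ties resolved to class 0.
    Returns (labels, fused probabilities).
    """
    if len(scores) < 2:
        raise ValueError("soft voting needs at least two classifiers")
    mats = [np.asarray(s, dtype=float) for s in scores]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("score matrices must share a shape")
    if psi is None:
        psi = np.full(len(mats), 1.0 / len(mats))
    else:
        psi = np.asarray(psi, dtype=float)
        if psi.shape != (len(mats),) or np.any(psi < 0) or psi.sum() <= 0:
            raise ValueError("psi must be nonnegative weights, one per classifier")
        psi = psi / psi.sum()
    fused = sum(w * m for w, m in zip(psi, mats))
    labels = fused.argmax(axis=1)  # argmax takes the first (class 0) on ties
    return labels, fused


def train(
    model,
    X,
    y: np.ndarray,
    subjects: np.ndarray,
    config: TrainConfig = TrainConfig(),
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
):
    """Subject-disjoint three-way training of one classifier.

    Subjects are split into train/validation/test partitions at the stated
    fractions; the model trains on the training partition with early
    stopping monitored on validation loss.  Returns
    ``(model, history, split)`` where ``split`` holds the index arrays.
    """
    from .workbench import subject_split  # local import to avoid a cycle

    y = np.asarray(y, dtype=int)
    subjects = np.asarray(subjects)
    split = subject_split(subjects, fractions=fractions, seed=config.seed)
    tr, va = split["train"], split["val"]

    def take(data, idx):
        if isinstance(data, tuple):
            return tuple(None if d is None else np.asarray(d)[idx] for d in data)
        return np.asarray(data)[idx]

    history = model.fit(take(X, tr), y[tr], take(X, va), y[va], config)
    return model, history, split
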
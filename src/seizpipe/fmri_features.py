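"""Image descriptors: smoothed pyramid histograms of oriented gradients
(S-PHOG) and a compact seed-deterministic convolutional embedder.

S-PHOG differs from the plain pyramid-HOG baseline in two ways: gradients
are computed on a Gaussian-smoothed image, and both the vote weight and the
orientation are locally regularized — the magnitude is normalized by the
summed magnitude of its neighborhood, and the orientation is the circular
mean of the neighborhood's unit gradient vectors.  Both changes damp the
descriptor's sensitivity to pixel-level noise.

The embedder is a two-stage 3-D convolutional encoder (widths 32 and 64,
kernel 3 per axis, max pooling) with fixed seed-initialized weights, read
out as a 256-dimensional globally pooled activation descriptor plus a
128-dimensional laterally pooled block — a synthetic stand-in for regional
connectivity features, labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synthgen import BrainImage

__all__ = [
    "SPHOGParams",
    "EmbedderConfig",
    "gaussian_smooth",
    "smoothed_gradients",
    "normalized_magnitude",
    "smoothed_orientation",
    "orientation_histogram",
    "sphog_descriptor",
    "phog_descriptor",
    "sphog_length",
    "deep_embed",
]


@dataclass
class SPHOGParams:
    sigma: float = 1.0
    n_bins: int = 9
    levels: tuple[int, ...] = (0, 1)
    signed: bool = False
    eps: float = 1e-12  # small enough to keep the descriptor scale-stable
    neigh: int = 3

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_bins < 2:
            raise ValueError("need at least 2 orientation bins")
        if not self.levels or tuple(self.levels) != tuple(range(len(self.levels))):
            raise ValueError("levels must be contiguous from 0")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.neigh < 1 or self.neigh % 2 == 0:
            raise ValueError("neigh must be odd")


def sphog_length(params: SPHOGParams) -> int:
    return params.n_bins * sum(4**level for level in params.levels)


def _as_2d(img: np.ndarray | BrainImage) -> np.ndarray:
    if isinstance(img, BrainImage):
        img = img.data
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:  # central slice of a volume
        img = img[:, :, img.shape[2] // 2]
    if img.ndim != 2:
        raise ValueError("expected a 2-D image or 3-D volume")
    return img


def gaussian_smooth(img: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian smoothing with reflect padding (mean preserving)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return ndimage.gaussian_filter(np.asarray(img, dtype=float), sigma=sigma, mode="reflect")


_DX = np.array([[-1.0, 0.0, 1.0]])  # centered derivative along columns (x)
_DY = np.array([[1.0], [0.0], [-1.0]])  # centered derivative along rows (y)


def smoothed_gradients(img: np.ndarray, sigma: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Centered-difference gradients of the Gaussian-smoothed image.

    The derivative masks are [-1, 0, 1] along x and its transpose-negated
    counterpart along y, applied by convolution with reflect padding.
    """
    img = np.asarray(img, dtype=float)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    sm = gaussian_smooth(img, sigma) if sigma > 0 else img
    ax = ndimage.convolve(sm, _DX, mode="reflect")
    ay = ndimage.convolve(sm, _DY, mode="reflect")
    return ax, ay


def normalized_magnitude(
    ax: np.ndarray, ay: np.ndarray, params: SPHOGParams = SPHOGParams()
) -> np.ndarray:
    """Gradient magnitude normalized by its summed neighborhood magnitude.

    A_new = A / (sum of A over the neigh x neigh neighborhood + eps); values
    lie in [0, 1] and an all-zero gradient field stays all zero.
    """
    if ax.shape != ay.shape:
        raise ValueError("gradient components must share a shape")
    a = np.sqrt(ax * ax + ay * ay)
    local = ndimage.uniform_filter(a, size=params.neigh, mode="reflect") * params.neigh**2
    return a / (local + params.eps)


def smoothed_orientation(
    ax: np.ndarray, ay: np.ndarray, params: SPHOGParams = SPHOGParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Neighborhood circular-mean orientation.

    Per pixel the raw angle atan2(Ay, Ax) is converted to a unit vector,
    vectors are averaged over the neighborhood, and the smoothed angle is the
    angle of the mean vector.  Returns ``(angle, degenerate)`` where the flag
    marks pixels whose mean vector vanished (opposite orientations cancelling);
    those angles are reported as 0.
    """
    if ax.shape != ay.shape:
        raise ValueError("gradient components must share a shape")
    angle = np.arctan2(ay, ax)
    ux = ndimage.uniform_filter(np.cos(angle), size=params.neigh, mode="reflect")
    uy = ndimage.uniform_filter(np.sin(angle), size=params.neigh, mode="reflect")
    norm = np.hypot(ux, uy)
    degenerate = norm < 1e-12
    out = np.where(degenerate, 0.0, np.arctan2(uy, ux))
    return out, degenerate


def orientation_histogram(
    mag: np.ndarray,
    ori: np.ndarray,
    region: tuple[slice, slice] | None,
    n_bins: int,
    signed: bool = False,
) -> np.ndarray:
    """Magnitude-weighted orientation histogram for one cell.

    Angles (radians) are wrapped into [0, 180) degrees for unsigned
    gradients or [0, 360) for signed ones, then voted into ``n_bins``
    equal-width bins weighted by the magnitude grid.
    """
    if region is not None:
        mag = mag[region]
        ori = ori[region]
    if mag.size == 0:
        return np.zeros(n_bins)
    span = 360.0 if signed else 180.0
    deg = np.degrees(ori) % span
    idx = np.minimum((deg / span * n_bins).astype(int), n_bins - 1)
    return np.bincount(idx.ravel(), weights=mag.ravel(), minlength=n_bins)


def _pyramid_histograms(
    mag: np.ndarray, ori: np.ndarray, params: SPHOGParams
) -> np.ndarray:
    h, w = mag.shape
    parts: list[np.ndarray] = []
    for level in params.levels:
        k = 2**level
        row_edges = np.linspace(0, h, k + 1).astype(int)
        col_edges = np.linspace(0, w, k + 1).astype(int)
        for i in range(k):
            for j in range(k):
                region = (
                    slice(row_edges[i], row_edges[i + 1]),
                    slice(col_edges[j], col_edges[j + 1]),
                )
                parts.append(
                    orientation_histogram(mag, ori, region, params.n_bins, params.signed)
                )
    return np.concatenate(parts)


def sphog_descriptor(
    img: np.ndarray | BrainImage, params: SPHOGParams = SPHOGParams()
) -> np.ndarray:
    """Smoothed pyramid histogram of oriented gradients, L1-normalized.

    Level l partitions the image into a 2^l x 2^l grid; each cell's histogram
    uses the neighborhood-normalized magnitude as vote weight and the
    circular-mean orientation as vote angle.  The concatenated vector is
    normalized to sum 1; a degenerate all-zero-gradient image yields the
    uniform vector.
    """
    img = _as_2d(img)
    deepest = 2 ** max(params.levels)
    if min(img.shape) < 2 * deepest:
        raise ValueError(
            f"image {img.shape} too small for pyramid level {max(params.levels)}"
        )
    ax, ay = smoothed_gradients(img, params.sigma)
    mag = normalized_magnitude(ax, ay, params)
    ori, _ = smoothed_orientation(ax, ay, params)
    vec = _pyramid_histograms(mag, ori, params)
    total = vec.sum()
    if total <= 0:
        return np.full(vec.size, 1.0 / vec.size)
    return vec / total


def phog_descriptor(
    img: np.ndarray | BrainImage, params: SPHOGParams = SPHOGParams()
) -> np.ndarray:
    """Unsmoothed pyramid-HOG baseline: raw centered-difference gradients,
    raw magnitude votes, raw per-pixel orientation.  Kept for ablation
    against the smoothed descriptor."""
    img = _as_2d(img)
    deepest = 2 ** max(params.levels)
    if min(img.shape) < 2 * deepest:
        raise ValueError(
            f"image {img.shape} too small for pyramid level {max(params.levels)}"
        )
    ax = ndimage.convolve(img, _DX, mode="reflect")
    ay = ndimage.convolve(img, _DY, mode="reflect")
    mag = np.sqrt(ax * ax + ay * ay)
    ori = np.arctan2(ay, ax)
    vec = _pyramid_histograms(mag, ori, params)
    total = vec.sum()
    if total <= 0:
        return np.full(vec.size, 1.0 / vec.size)
    return vec / total


# ---------------------------------------------------------------------------
# compact deep embedder


@dataclass
class EmbedderConfig:
    kernel: int = 3
    conv_widths: tuple[int, int] = (32, 64)
    out_dims: tuple[int, int] = (256, 128)
    seed: int = 0


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


def _conv3d(vol: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Valid-region 3-D convolution of a (Cin, H, W, D) volume with
    (Cout, Cin, k, k, kd) weights via im2col."""
    cin, h, w, d = vol.shape
    cout, _, k, _, kd = weights.shape
    win = np.lib.stride_tricks.sliding_window_view(vol, (k, k, kd), axis=(1, 2, 3))
    # win: (cin, H', W', D', k, k, kd) -> (H'*W'*D', cin*k*k*kd)
    hp, wp, dp = win.shape[1:4]
    cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(hp * wp * dp, -1)
    out = cols @ weights.reshape(cout, -1).T
    return out.T.reshape(cout, hp, wp, dp)


def _maxpool3d(vol: np.ndarray, size: int = 2) -> np.ndarray:
    c, h, w, d = vol.shape
    h2, w2, d2 = (max(h // size, 1), max(w // size, 1), max(d // size, 1))
    vol = vol[:, : h2 * min(size, h), : w2 * min(size, w), : d2 * min(size, d)]
    sh, sw, sd = min(size, h), min(size, w), min(size, d)
    return vol.reshape(c, h2, sh, w2, sw, d2, sd).max(axis=(2, 4, 6))


class DeepEmbedder:
    """Seed-deterministic random-projection conv encoder (no training).

    Weights are frozen at He-initialization from the seed; the same
    (seed, image) pair always maps to the same 384-vector.
    """

    def __init__(self, config: EmbedderConfig = EmbedderConfig()):
        self.config = config
        k = config.kernel
        c1, c2 = config.conv_widths
        rng = np.random.default_rng(config.seed)
        self.w1 = _he_init(rng, (c1, 1, k, k, k), fan_in=k**3)
        self.w2 = _he_init(rng, (c2, c1, k, k, k), fan_in=c1 * k**3)
        d1, d2 = config.out_dims
        # readout projections: global stats -> activation block, lateral
        # stats -> "connectivity" block
        self.p_global = _he_init(rng, (2 * c2, d1), fan_in=2 * c2)
        self.p_region = _he_init(rng, (2 * c2, d2), fan_in=2 * c2)

    def __call__(self, img: np.ndarray | BrainImage) -> np.ndarray:
        if isinstance(img, BrainImage):
            img = img.data
        vol = np.asarray(img, dtype=float)
        if vol.ndim == 2:
            vol = vol[:, :, None]
        if vol.ndim != 3 or min(vol.shape[:2]) < 8:
            raise ValueError("embedder needs a volume with in-plane dims >= 8")
        k = self.config.kernel
        pad = k // 2
        x = np.pad(vol[None], ((0, 0), (pad, pad), (pad, pad), (pad, pad)), mode="reflect")
        x = np.maximum(_conv3d(x, self.w1), 0.0)
        x = _maxpool3d(x)
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (pad, pad)), mode="reflect")
        x = np.maximum(_conv3d(x, self.w2), 0.0)
        x = _maxpool3d(x)

        c = x.shape[0]
        flat = x.reshape(c, -1)
        g_stats = np.concatenate([flat.mean(axis=1), flat.std(axis=1)])
        # lateral mask: left-hemisphere half of the width axis, a fixed
        # anatomical-style region (synthetic connectivity stand-in)
        left = x[:, :, : max(x.shape[2] // 2, 1), :].reshape(c, -1)
        r_stats = np.concatenate([left.mean(axis=1), left.std(axis=1)])
        return np.concatenate([g_stats @ self.p_global, r_stats @ self.p_region])


def deep_embed(img: np.ndarray | BrainImage, config: EmbedderConfig = EmbedderConfig()) -> np.ndarray:
    """Embed a brain image as a 256 + 128 = 384-dimensional vector."""
    return DeepEmbedder(config)(img)
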
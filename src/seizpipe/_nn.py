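"""Minimal NumPy neural-network primitives used by the classifier module.

Convolutions are implemented with im2col + matmul (reflect padding, stride
1, "same" output size); only the dense classification head is trained, with
hand-written backpropagation and Adam.  Everything is deterministic given
the seeds supplied by the caller.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "he_init",
    "conv1d",
    "conv2d",
    "depthwise_conv1d",
    "depthwise_conv2d",
    "maxpool1d",
    "maxpool2d",
    "softmax",
    "MLPHead",
]


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


def conv1d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """x (N, Cin, L), w (Cout, Cin, k) -> (N, Cout, L); reflect padding."""
    n, cin, length = x.shape
    cout, _, k = w.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)), mode="reflect")
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (N,Cin,L,k)
    cols = win.transpose(0, 2, 1, 3).reshape(n * length, cin * k)
    out = cols @ w.reshape(cout, -1).T
    return out.reshape(n, length, cout).transpose(0, 2, 1)


def depthwise_conv1d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """x (N, C, L), w (C, k): per-channel convolution."""
    c, k = w.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)), mode="reflect")
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
    return np.einsum("nclk,ck->ncl", win, w)


def conv2d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """x (N, Cin, H, W), w (Cout, Cin, k, k) -> (N, Cout, H, W)."""
    n, cin, h, wd = x.shape
    cout, _, k, _ = w.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="reflect")
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, cin * k * k)
    out = cols @ w.reshape(cout, -1).T
    return out.reshape(n, h, wd, cout).transpose(0, 3, 1, 2)


def depthwise_conv2d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """x (N, C, H, W), w (C, k, k): per-channel convolution."""
    c, k, _ = w.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="reflect")
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return np.einsum("nchwij,cij->nchw", win, w)


def maxpool1d(x: np.ndarray, size: int = 2) -> np.ndarray:
    n, c, length = x.shape
    l2 = length // size
    return x[:, :, : l2 * size].reshape(n, c, l2, size).max(axis=3)


def maxpool2d(x: np.ndarray, size: int = 2) -> np.ndarray:
    n, c, h, w = x.shape
    h2, w2 = h // size, w // size
    return x[:, :, : h2 * size, : w2 * size].reshape(n, c, h2, size, w2, size).max(axis=(3, 5))


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MLPHead:
    """Fully connected softmax classifier trained with Adam on cross-entropy.

    ReLU hidden layers with inverted dropout after the first hidden layer.
    """

    def __init__(
        self,
        in_dim: int,
        hidden: tuple[int, ...] = (128, 64),
        n_classes: int = 2,
        dropout: float = 0.3,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        dims = (in_dim, *hidden, n_classes)
        self.weights = [he_init(rng, (a, b), fan_in=a) for a, b in zip(dims, dims[1:])]
        self.biases = [np.zeros(b) for b in dims[1:]]
        self.dropout = dropout
        self._adam_m = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_v = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_t = 0

    # -- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray, rng: np.random.Generator | None = None):
        acts = [x]
        masks: list[np.ndarray | None] = []
        h = x
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            if i < n_layers - 1:
                h = np.maximum(z, 0.0)
                if rng is not None and self.dropout > 0 and i == 0:
                    mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                acts.append(h)
            else:
                probs = softmax(z)
        return probs, acts, masks

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        probs, _, _ = self._forward(np.asarray(x, dtype=float))
        return probs

    @staticmethod
    def _loss(probs: np.ndarray, y: np.ndarray) -> float:
        return float(-np.log(probs[np.arange(len(y)), y] + 1e-12).mean())

    def _step(self, x: np.ndarray, y: np.ndarray, lr: float, rng: np.random.Generator):
        probs, acts, masks = self._forward(x, rng)
        n = len(y)
        delta = probs.copy()
        delta[np.arange(n), y] -= 1.0
        delta /= n
        grads_w: list[np.ndarray] = [None] * len(self.weights)
        grads_b: list[np.ndarray] = [None] * len(self.biases)
        for i in range(len(self.weights) - 1, -1, -1):
            grads_w[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
                delta = delta * (acts[i] > 0)
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
        self._adam(grads_w + grads_b, lr)
        return self._loss(probs, y)

    def _adam(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        params = self.weights + self.biases
        self._adam_t += 1
        t = self._adam_t
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mh = m / (1 - beta1**t)
            vh = v / (1 - beta2**t)
            p -= lr * mh / (np.sqrt(vh) + eps)

    # -- training loop ------------------------------------------------------

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        x_val: np.ndarray,
        y_val: np.ndarray,
        lr: float = 1e-3,
        batch_size: int = 32,
        epochs: int = 100,
        patience: int = 10,
        seed: int = 0,
    ) -> dict[str, list[float]]:
        """Mini-batch Adam with early stopping on validation loss; the best
        weights are restored at the end."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(seed)
        history: dict[str, list[float]] = {
            "train_loss": [], "val_loss": [], "train_acc": [], "val_acc": [],
        }
        best_val = np.inf
        best_state = None
        stale = 0
        for _ in range(epochs):
            order = rng.permutation(len(y))
            for start in range(0, len(y), batch_size):
                idx = order[start : start + batch_size]
                self._step(x[idx], y[idx], lr, rng)
            p_tr = self.predict_proba(x)
            p_va = self.predict_proba(x_val)
            tl, vl = self._loss(p_tr, y), self._loss(p_va, y_val)
            history["train_loss"].append(tl)
            history["val_loss"].append(vl)
            history["train_acc"].append(float((p_tr.argmax(1) == y).mean()))
            history["val_acc"].append(float((p_va.argmax(1) == y_val).mean()))
            if vl < best_val - 1e-6:
                best_val = vl
                best_state = ([w.copy() for w in self.weights], [b.copy() for b in self.biases])
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break
        if best_state is not None:
            self.weights, self.biases = best_state
        return history
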
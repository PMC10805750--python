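"""Compact numpy neural-network core for 1-D signals.

Implements exactly what the translation and classification models need:
strided 1-D convolution with explicit forward/backward (im2col), leaky-ReLU /
tanh activations, nearest-neighbour upsampling, global average pooling, a
dense head, the Adam optimizer, and the binary/categorical losses. Arrays are
(N, C, L). Everything is deterministic given the initialization seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "truncated_normal", "Conv1d", "LeakyReLU", "Tanh", "Upsample1d",
    "GlobalAvgPool", "Dense", "Sequential", "Adam",
    "bce_with_logits", "mse_loss", "l1_loss", "softmax_cross_entropy",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def truncated_normal(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    """Normal draws re-sampled until within 2 SD (TensorFlow-style truncation)."""
    out = rng.normal(0.0, sd, size=shape)
    bad = np.abs(out) > 2 * sd
    while np.any(bad):
        out[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(out) > 2 * sd
    return out


def _same_pad(length: int, kernel: int, stride: int) -> tuple[int, int, int]:
    out_len = -(-length // stride)  # ceil
    total = max(0, (out_len - 1) * stride + kernel - length)
    left = total // 2
    return out_len, left, total - left


class Conv1d:
    """Strided 1-D convolution with 'same' padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None, init_sd: float | None = None,
                 trunc: bool = False):
        rng = rng or np.random.default_rng(0)
        if init_sd is None:
            init_sd = np.sqrt(2.0 / (in_ch * kernel))  # He fan-in
        w = (truncated_normal(rng, (out_ch, in_ch, kernel), init_sd) if trunc
             else rng.normal(0.0, init_sd, size=(out_ch, in_ch, kernel)))
        self.w = Param(w)
        self.b = Param(np.zeros(out_ch))
        self.stride = stride
        self.kernel = kernel
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        k, s = self.kernel, self.stride
        out_len, pl, pr = _same_pad(length, k, s)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)[:, :, ::s, :]
        y = np.einsum("nclk,ock->nol", cols, self.w.value, optimize=True)
        y += self.b.value[None, :, None]
        self._cache = (cols, xp.shape, pl, length)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, pl, length = self._cache
        s = self.stride
        self.w.grad += np.einsum("nclk,nol->ock", cols, dy, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2))
        dxp = np.zeros(xp_shape)
        out_len = dy.shape[2]
        pos0 = np.arange(out_len) * s
        for t in range(self.kernel):
            # dL/dx at positions pos0 + t receives dy . W[:, :, t]
            contrib = np.einsum("nol,oc->ncl", dy, self.w.value[:, :, t], optimize=True)
            dxp[:, :, pos0 + t] += contrib
        return dxp[:, :, pl : pl + length]


class LeakyReLU:
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.alpha * dy)


class Tanh:
    def __init__(self):
        self._y = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * (1.0 - self._y**2)


class Upsample1d:
    """Nearest-neighbour upsampling; backward is block summation."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(x, self.factor, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, length = dy.shape
        return dy.reshape(n, c, length // self.factor, self.factor).sum(axis=3)


class GlobalAvgPool:
    def __init__(self):
        self._len = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._len = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._len, axis=2) / self._len


class Dense:
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None,
                 init_sd: float | None = None, trunc: bool = False):
        rng = rng or np.random.default_rng(0)
        if init_sd is None:
            init_sd = np.sqrt(2.0 / in_dim)
        w = (truncated_normal(rng, (in_dim, out_dim), init_sd) if trunc
             else rng.normal(0.0, init_sd, size=(in_dim, out_dim)))
        self.w = Param(w)
        self.b = Param(np.zeros(out_dim))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_with_logits(logits: np.ndarray, target: float | np.ndarray):
    """Mean sigmoid cross-entropy; returns (loss, dloss/dlogits)."""
    t = np.broadcast_to(np.asarray(target, dtype=float), logits.shape)
    # log(1 + e^-|x|) + max(x, 0) - x*t  (numerically stable)
    loss = np.mean(np.log1p(np.exp(-np.abs(logits))) + np.maximum(logits, 0) - logits * t)
    sig = 1.0 / (1.0 + np.exp(-logits))
    return float(loss), (sig - t) / logits.size


def mse_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / pred.size


def l1_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / pred.size


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over integer labels; returns (loss, dlogits, probs)."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(np.maximum(probs[np.arange(n), labels], 1e-12))))
    d = probs.copy()
    d[np.arange(n), labels] -= 1.0
    return loss, d / n, probs
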
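"""Minimal numpy CNN engine: layers with explicit forward/backward passes.

Supports exactly what the reading-network experiments require —
im2col convolution, rectification, max-pooling, global average pooling
and a linear readout — trained by stochastic gradient descent with
momentum on a softmax cross-entropy loss.  Arrays are float32 NCHW.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv_out_size(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


class Layer:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Param:
    """A weight array together with its gradient and momentum buffer."""

    __slots__ = ("value", "grad", "vel")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.vel = np.zeros_like(value)


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 pad: int, rng: np.random.Generator):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s, self.p = kernel, stride, pad
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_ch, in_ch, kernel, kernel))
        self.W = Param(w.astype(np.float32))
        self.b = Param(np.zeros(out_ch, dtype=np.float32))
        self._cache = None
        #: the input-most layer can skip folding dx (nothing consumes it)
        self.needs_dx = True

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, s, p = self.k, self.s, self.p
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
        cols = cols.reshape(n, ho, wo, c * k * k)
        wm = self.W.value.reshape(self.out_ch, -1)
        y = cols @ wm.T + self.b.value
        if train:
            self._cache = (cols, x.shape)
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, dy):
        cols, xshape = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.s, self.p
        ho, wo = dy.shape[2], dy.shape[3]
        dyt = dy.transpose(0, 2, 3, 1)
        flat_dy = dyt.reshape(-1, self.out_ch)
        flat_cols = cols.reshape(-1, cols.shape[-1])
        self.W.grad += (flat_dy.T @ flat_cols).reshape(self.W.value.shape)
        self.b.grad += flat_dy.sum(axis=0)
        if not self.needs_dx:
            self._cache = None
            return None
        wm = self.W.value.reshape(self.out_ch, -1)
        dcols = (dyt @ wm).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cache = None
        return dxp[:, :, p:p + h, p:p + w]


class ReLU(Layer):
    def forward(self, x, train=False):
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.s, self.p = kernel, stride, pad

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, s, p = self.k, self.s, self.p
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        flat = win.reshape(n, c, ho, wo, k * k)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape, (ho, wo))
        return y

    def backward(self, dy):
        idx, (n, c, h, w), (ho, wo) = self._cache
        k, s, p = self.k, self.s, self.p
        hp, wp = h + 2 * p, w + 2 * p
        di, dj = idx // k, idx % k
        rows = np.arange(ho)[None, None, :, None] * s + di
        cols = np.arange(wo)[None, None, None, :] * s + dj
        flat_idx = (rows * wp + cols).reshape(n * c, -1)
        dxp = np.zeros((n * c, hp * wp), dtype=np.float32)
        np.add.at(dxp, (np.arange(n * c)[:, None], flat_idx),
                  dy.reshape(n * c, -1))
        dxp = dxp.reshape(n, c, hp, wp)
        self._cache = None
        return dxp[:, :, p:p + h, p:p + w]


class GlobalAvgPool(Layer):
    """NCHW -> NC channel-wise spatial average."""

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w),
                               (n, c, h, w)).astype(np.float32)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, scale: float | None = None):
        scale = np.sqrt(1.0 / in_features) if scale is None else scale
        self.W = Param(rng.normal(0.0, scale,
                                  size=(out_features, in_features)
                                  ).astype(np.float32))
        self.b = Param(np.zeros(out_features, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy):
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value


def softmax_cross_entropy(logits: np.ndarray,
                          labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean loss and gradient w.r.t. logits for integer class labels."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(probs[np.arange(n), labels] + 1e-12).mean()
    dlogits = probs
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(np.float32)


class SGD:
    def __init__(self, params: list[Param], lr: float,
                 momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p in self.params:
            p.vel[...] = self.momentum * p.vel - self.lr * p.grad
            p.value += p.vel
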
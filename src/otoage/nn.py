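"""Minimal convolutional-network machinery on numpy.

Implements exactly the layer set needed by the age-regression model: 2-D
convolution (im2col), batch normalization with freezable running statistics,
ReLU, global average pooling, dropout, dense layers, and the Adam optimizer.
Every layer exposes a backward pass, and the chain can be differentiated all
the way to the input image, which is what the gradient-attribution methods
require.  The ReLU backward pass supports the "guided" variant (only positive
gradients propagate through active units).

Arrays are NCHW float32 for the spatial layers and (N, features) for the
dense stage.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "GlobalAvgPool",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
]


class Param:
    """A trainable array plus its gradient accumulator."""

    __slots__ = ("value", "grad", "weight_decay")

    def __init__(self, value: np.ndarray, weight_decay: bool = True):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        # biases and BN offsets are conventionally exempt from L2
        self.weight_decay = weight_decay


class Layer:
    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv2D(Layer):
    """k x k convolution, He-initialised, 'same'-style zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.w = Param(w)
        self.b = Param(np.zeros(c_out), weight_decay=False)
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride, self.pad = kernel, stride, pad
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # (N, C, Ho, Wo, k, k) -> (N, Ho, Wo, C*k*k)
        win = win.transpose(0, 2, 3, 1, 4, 5)
        n, ho, wo = win.shape[:3]
        return np.ascontiguousarray(win).reshape(n, ho, wo, c * k * k)

    def forward(self, x, training=False, rng=None):
        x = np.asarray(x, dtype=np.float32)
        cols = self._im2col(x)
        self._cols, self._xshape = cols, x.shape
        out = cols @ self.w.value + self.b.value
        return out.transpose(0, 3, 1, 2)

    def backward(self, grad, guided=False):
        n, f, ho, wo = grad.shape
        g = grad.transpose(0, 2, 3, 1)               # (N, Ho, Wo, F)
        cols = self._cols
        self.w.grad += cols.reshape(-1, cols.shape[-1]).T @ g.reshape(-1, f)
        self.b.grad += g.sum(axis=(0, 1, 2))
        dcols = g @ self.w.value.T                   # (N, Ho, Wo, C*k*k)
        # col2im scatter-add
        _, c, h, w = self._xshape
        p, k, s = self.pad, self.k, self.stride
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        dcols = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, :, :, i, j]
        return dxp[:, :, p:p + h, p:p + w]

    def params(self):
        return [self.w, self.b]


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (N, H, W).

    With ``frozen_stats`` the running statistics are never updated and the
    forward pass always normalizes with them (so a forward pass is a fixed
    affine map per channel); otherwise batch statistics are used during
    training and running statistics at inference.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 frozen_stats: bool = False):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels), weight_decay=False)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.frozen_stats = frozen_stats
        self._cache = None

    def forward(self, x, training=False, rng=None):
        g = self.gamma.value[None, :, None, None]
        b = self.beta.value[None, :, None, None]
        if training and not self.frozen_stats:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
            self._cache = ("batch", xhat, inv, x.shape)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean[None, :, None, None]) * inv[None, :, None, None]
            self._cache = ("running", xhat, inv, x.shape)
        return g * xhat + b

    def backward(self, grad, guided=False):
        mode, xhat, inv, shape = self._cache
        g = self.gamma.value
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        if mode == "running":
            return grad * (g * inv)[None, :, None, None]
        n, _, h, w = shape
        m = n * h * w
        gxh = grad * g[None, :, None, None]
        s1 = gxh.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (gxh * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (inv[None, :, None, None] / m) * (m * gxh - s1 - xhat * s2)

    def params(self):
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad, guided=False):
        g = grad * self._mask
        if guided:
            g = np.where(g > 0, g, 0.0)
        return g


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad, guided=False):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), self._shape).copy()


class Dropout(Layer):
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode requires an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad, guided=False):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad, guided=False):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int,
                 rng: np.random.Generator | None = None,
                 bias_init: np.ndarray | None = None):
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out))
        self.w = Param(w)
        b = np.zeros(c_out) if bias_init is None else np.asarray(bias_init, float)
        self.b = Param(b, weight_decay=False)

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad, guided=False):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T

    def params(self):
        return [self.w, self.b]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, grad, guided=False):
        for layer in reversed(self.layers):
            grad = layer.backward(grad, guided=guided)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


class Adam:
    """Adam with optional L2 penalty added to the gradient (loss + l2*||w||^2)."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, l2: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps, self.l2 = lr, beta1, beta2, eps, l2
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.l2 and p.weight_decay:
                g = g + 2.0 * self.l2 * p.value
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
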
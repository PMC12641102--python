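"""Minimal NumPy neural-network layers with hand-written backward passes.

Implements exactly the operations the BMD networks need: 3x3/1x1 "same"
convolutions (im2col + BLAS matmul), batch normalization, ReLU, sigmoid,
2x2 max-pooling, 2x2 nearest-neighbour up-sampling, global average pooling,
a dense layer, and an Adam optimizer.  Arrays are NCHW; float32 by default
(float64 supported for gradient-checking).

Each layer caches its forward inputs, so the calling pattern is one
``forward`` followed by at most one ``backward`` per step.  Parameter
gradients are accumulated into ``Param.grad`` and zeroed by the optimizer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Conv2d", "BatchNorm2d", "ReLU", "Sigmoid",
    "MaxPool2", "Upsample2", "GlobalAvgPool", "Dense", "Adam",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) -> (N, C*9, H*W) patch matrix for a 3x3 same-pad conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    s = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (n, c, 3, 3, h, w), (s[0], s[1], s[2], s[3], s[2], s[3]))
    return win.reshape(n, c * 9, h * w)


def _col2im3(dcols: np.ndarray, shape: tuple) -> np.ndarray:
    """Adjoint of _im2col3: scatter-add patch gradients back to the image."""
    n, c, h, w = shape
    d = dcols.reshape(n, c, 3, 3, h, w)
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    for i in range(3):
        for j in range(3):
            dxp[:, :, i:i + h, j:j + w] += d[:, :, i, j]
    return dxp[:, :, 1:h + 1, 1:w + 1]


class Conv2d(Layer):
    """Same-padded convolution, kernel size 1 or 3, He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        if k not in (1, 3):
            raise ValueError("kernel size must be 1 or 3")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        std = np.sqrt(2.0 / (c_in * k * k))
        self.W = Param(rng.normal(0.0, std, (c_out, c_in * k * k)).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        cols = x.reshape(n, c, h * w) if self.k == 1 else _im2col3(x)
        y = np.matmul(self.W.value, cols) + self.b.value[:, None]
        self._cache = (cols, x.shape)
        return y.reshape(n, self.c_out, h, w)

    def backward(self, dy):
        cols, xshape = self._cache
        n, c, h, w = xshape
        dyf = dy.reshape(n, self.c_out, h * w)
        self.W.grad += np.einsum("nop,nkp->ok", dyf, cols)
        self.b.grad += dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.W.value.T, dyf)
        if self.k == 1:
            return dcols.reshape(xshape)
        return _col2im3(dcols, xshape)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, dy):
        xhat, inv_std = self._cache
        n, c, h, w = dy.shape
        m = n * h * w
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = (self.gamma.value * inv_std)[:, None, None]
        sum_dy = dy.sum(axis=(0, 2, 3))[:, None, None]
        sum_dy_xhat = (dy * xhat).sum(axis=(0, 2, 3))[:, None, None]
        return g * (dy - sum_dy / m - xhat * sum_dy_xhat / m)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        # clip keeps exp from overflowing in float32 on wild logits
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class MaxPool2(Layer):
    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._xshape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class Upsample2(Layer):
    def forward(self, x, train=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h2, w2 = dy.shape
        return dy.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C) spatial mean."""

    def forward(self, x, train=False):
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._xshape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), self._xshape).copy()


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        std = np.sqrt(2.0 / d_in)
        self.W = Param(rng.normal(0.0, std, (d_in, d_out)).astype(dtype))
        self.b = Param(np.zeros(d_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
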
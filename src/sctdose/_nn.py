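"""Minimal numpy neural-network backend for the image-translation model.

Implements exactly what the conditional-GAN trainer needs — 2D convolution,
instance normalization, nearest-neighbour upsampling, the usual activations
and Adam — for single samples (batch size one, matching the training
regime). Everything is plain numpy, so runs are bit-reproducible for a
fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Adam",
    "Conv2d",
    "InstanceNorm",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "Upsample2x",
    "Sequential",
    "bce_with_logits",
    "bce_with_logits_grad",
]

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Adam:
    """Adam with the image-translation-GAN conventions (lr 2e-4, beta1 0.5)."""

    def __init__(self, params, lr=2e-4, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p in self.params:
            p.m[...] = self.b1 * p.m + (1.0 - self.b1) * p.grad
            p.v[...] = self.b2 * p.v + (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)


def _im2col(xp: np.ndarray, k: int, stride: int):
    """(C, Hp, Wp) -> (Ho*Wo, C*k*k) column matrix."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (C, Ho, Wo, k, k)
    c, ho, wo = win.shape[:3]
    cols = win.transpose(1, 2, 0, 3, 4).reshape(ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


class Conv2d:
    def __init__(self, c_in, c_out, k=4, stride=2, pad=1, rng=None):
        scale = 0.02  # pix2pix-style N(0, 0.02) init
        self.W = Param(rng.normal(0.0, scale, size=(c_out, c_in, k, k)))
        self.b = Param(np.zeros(c_out))
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p))) if p else x
        cols, ho, wo = _im2col(xp, self.k, self.stride)
        wflat = self.W.value.reshape(self.W.value.shape[0], -1)
        y = cols @ wflat.T + self.b.value
        self._cache = (cols, x.shape, xp.shape, ho, wo)
        return np.ascontiguousarray(y.reshape(ho, wo, -1).transpose(2, 0, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, xp_shape, ho, wo = self._cache
        c_out = dy.shape[0]
        dyf = dy.transpose(1, 2, 0).reshape(ho * wo, c_out)
        wflat = self.W.value.reshape(c_out, -1)
        self.W.grad += (dyf.T @ cols).reshape(self.W.value.shape)
        self.b.grad += dyf.sum(axis=0)
        dcols = (dyf @ wflat).reshape(ho, wo, x_shape[0], self.k, self.k)
        dxp = np.zeros(xp_shape, dtype=DTYPE)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + ho * s : s, j : j + wo * s : s] += dcols[
                    :, :, :, i, j
                ].transpose(2, 0, 1)
        p = self.pad
        return dxp[:, p : xp_shape[1] - p, p : xp_shape[2] - p] if p else dxp


class InstanceNorm:
    """Per-channel normalization over the spatial extent (batch size one)."""

    def __init__(self, c, eps=1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps
        self._cache = None

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        std = np.sqrt(var + self.eps)
        xhat = (x - mu) / std
        self._cache = (xhat, std)
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        n = xhat.shape[1] * xhat.shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2))
        self.beta.grad += dy.sum(axis=(1, 2))
        dxhat = dy * self.gamma.value[:, None, None]
        # dx for y = (x - mu)/std with mu, std functions of x
        term = (
            dxhat
            - dxhat.mean(axis=(1, 2), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(1, 2), keepdims=True)
        )
        return term / std


class LeakyReLU:
    params = ()

    def __init__(self, slope=0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh:
    params = ()

    def __init__(self):
        self._y = None

    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y**2)


class Upsample2x:
    """Nearest-neighbour ×2 upsampling."""

    params = ()

    def forward(self, x):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        c, h, w = dy.shape
        return dy.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    @property
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def bce_with_logits(z: np.ndarray, target: float) -> float:
    """Mean binary cross-entropy on logits against a constant target."""
    return float(np.mean(np.logaddexp(0.0, z) - target * z))


def bce_with_logits_grad(z: np.ndarray, target: float) -> np.ndarray:
    sig = 1.0 / (1.0 + np.exp(-z))
    return ((sig - target) / z.size).astype(DTYPE)
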
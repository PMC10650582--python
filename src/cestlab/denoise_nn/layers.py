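"""Minimal NumPy layers with explicit forward/backward passes.

All tensors are (N, C, H, W) float64.  Each layer caches what its backward
pass needs; ``backward`` consumes the upstream gradient and accumulates
parameter gradients in-place.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Param", "Conv2d", "ReLU", "MaxPool2", "UpsampleNearest2"]


class Param:
    """Trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv2d:
    """Same-padding 2D convolution (odd kernel), He-initialised."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int,
                 rng: np.random.Generator):
        if ksize % 2 == 0:
            raise ValueError("kernel size must be odd")
        fan_in = in_ch * ksize * ksize
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_ch, in_ch, ksize, ksize))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_ch))
        self.ksize = ksize
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.ksize
        pad = k // 2
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))  # n,c,h,w,k,k
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        wmat = self.weight.value.reshape(len(self.bias.value), -1)
        y = cols @ wmat.T + self.bias.value
        self._cache = (cols, x.shape)
        return y.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n, c, h, w = x_shape
        k = self.ksize
        pad = k // 2
        out_ch = dy.shape[1]
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(n * h * w, out_ch)
        self.weight.grad += (dy_mat.T @ cols).reshape(self.weight.value.shape)
        self.bias.grad += dy_mat.sum(axis=0)
        dcols = (dy_mat @ self.weight.value.reshape(out_ch, -1))
        dcols = dcols.reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + h, kj:kj + w] += \
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return dxp[:, :, pad:pad + h, pad:pad + w]


class ReLU:
    def __init__(self):
        self._mask = None

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool2:
    """2x2 max pooling with stride 2 (spatial dims must be even)."""

    def __init__(self):
        self._cache = None

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial size must be even for 2x2 pooling")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = blocks.max(axis=(3, 5))
        self._cache = (blocks, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        blocks, y = self._cache
        mask = blocks == y[:, :, :, None, :, None]
        # split gradient evenly across ties (rare with float activations)
        mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        db = mask * dy[:, :, :, None, :, None]
        n, c, h2, _, w2, _ = blocks.shape
        return db.reshape(n, c, h2 * 2, w2 * 2)


class UpsampleNearest2:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
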
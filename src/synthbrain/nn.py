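"""Minimal 3D convolutional network library in NumPy.

Implements exactly the operations needed by the segmentation suite — 3D
convolution (im2col + BLAS matmul), channel normalization, ELU, 2x max
pooling, nearest-neighbour upsampling, channel concatenation, softmax and
global max pooling — each with a hand-written backward pass, plus the Adam
optimizer. Tensors are channels-first ``(C, D, H, W)`` float32 without a
batch axis (training uses minibatches of one volume).

The library is deliberately small: it targets desk-scale networks (a few
levels, tens of features) and deterministic CPU execution, not large-scale
training.
"""

from __future__ import annotations

import hashlib
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv3d",
    "ChannelNorm",
    "ELU",
    "MaxPool2",
    "Upsample2",
    "Softmax",
    "GlobalMaxPool",
    "Adam",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base class: forward caches what backward needs."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv3d(Layer):
    """Same-padded 3D convolution over channels-first volumes."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        need_input_grad: bool = True,
    ) -> None:
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.need_input_grad = need_input_grad
        fan_in = c_in * kernel**3
        # He initialization suits the ELU/ReLU family
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.W = Param(w, "conv.W")
        self.b = Param(np.zeros(c_out), "conv.b")
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    @staticmethod
    def _im2col_static(x: np.ndarray, k: int) -> np.ndarray:
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        # (C, D, H, W, k, k, k) -> (C*k^3, N)
        c, d, h, w = x.shape
        return (
            win.transpose(0, 4, 5, 6, 1, 2, 3).reshape(c * k**3, d * h * w)
        ).astype(np.float32, copy=False)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        cols = self._im2col_static(np.asarray(x, dtype=np.float32), self.k)
        self._cols = cols
        y = self.W.value @ cols + self.b.value[:, None]
        return y.reshape(self.c_out, *x.shape[1:])

    def backward(self, gy: np.ndarray) -> np.ndarray | None:
        c, d, h, w = self._shape
        gy = np.ascontiguousarray(gy, dtype=np.float32)
        gy_mat = gy.reshape(self.c_out, -1)
        self.W.grad += gy_mat @ self._cols.T
        self.b.grad += gy_mat.sum(axis=1)
        self._cols = None
        if not self.need_input_grad:
            return None
        # input gradient = same-padded convolution of gy with the spatially
        # flipped kernels, channels transposed
        k3 = self.k**3
        w_t = self.W.value.reshape(self.c_out, self.c_in, k3)[:, :, ::-1]
        w_t = np.ascontiguousarray(w_t.transpose(1, 0, 2)).reshape(self.c_in, self.c_out * k3)
        gx = w_t @ Conv3d._im2col_static(gy, self.k)
        return gx.reshape(c, d, h, w)


class ChannelNorm(Layer):
    """Per-channel normalization over the spatial axes with learnable
    scale/shift. With minibatches of one volume this is the batch-statistics
    normalization used during training (no running averages are kept)."""

    def __init__(self, c: int, eps: float = 1e-5) -> None:
        self.eps = eps
        self.g = Param(np.ones(c), "norm.g")
        self.b = Param(np.zeros(c), "norm.b")

    def params(self) -> list[Param]:
        return [self.g, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        ax = (1, 2, 3)
        self._mu = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xn = (x - self._mu) * self._istd
        return self.g.value[:, None, None, None] * self._xn + self.b.value[:, None, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        ax = (1, 2, 3)
        n = gy[0].size
        self.g.grad += (gy * self._xn).sum(axis=ax)
        self.b.grad += gy.sum(axis=ax)
        gxn = gy * self.g.value[:, None, None, None]
        gx = (
            gxn
            - gxn.mean(axis=ax, keepdims=True)
            - self._xn * (gxn * self._xn).mean(axis=ax, keepdims=True)
        ) * self._istd
        return gx.astype(np.float32, copy=False)


class ELU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        y = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
        self._y, self._pos = y, x > 0
        return y.astype(np.float32, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._pos, gy, gy * (self._y + 1.0)).astype(np.float32, copy=False)


class MaxPool2(Layer):
    """2x2x2 max pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        assert d % 2 == 0 and h % 2 == 0 and w % 2 == 0, "pool needs even dims"
        blocks = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        flat = blocks.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        c, d, h, w = self._shape
        flat = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
        np.put_along_axis(flat, self._arg[..., None], gy[..., None], axis=-1)
        blocks = flat.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
        return blocks.reshape(c, d, h, w)


class Upsample2(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        c, d, h, w = gy.shape
        return (
            gy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))
        ).astype(np.float32, copy=False)


class Softmax(Layer):
    """Softmax over the channel axis."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        e = np.exp(x - x.max(axis=0, keepdims=True))
        self._y = (e / e.sum(axis=0, keepdims=True)).astype(np.float32)
        return self._y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        dot = (gy * self._y).sum(axis=0, keepdims=True)
        return (self._y * (gy - dot)).astype(np.float32, copy=False)


class GlobalMaxPool(Layer):
    """Per-channel global max over the spatial axes -> vector."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = x.shape[0]
        flat = x.reshape(c, -1)
        self._arg = flat.argmax(axis=1)
        self._shape = x.shape
        return flat[np.arange(c), self._arg].copy()

    def backward(self, gy: np.ndarray) -> np.ndarray:
        c = self._shape[0]
        flat = np.zeros((c, int(np.prod(self._shape[1:]))), dtype=np.float32)
        flat[np.arange(c), self._arg] = gy
        return flat.reshape(self._shape)


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 1e-5,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def params_checksum(params: Sequence[Param]) -> str:
    """SHA-256 over the concatenated parameter bytes (frozen-weight audits)."""
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.value).tobytes())
    return h.hexdigest()
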
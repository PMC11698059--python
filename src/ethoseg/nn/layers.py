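"""1-D layers with explicit forward/backward passes (float32).

Conventions: activations are ``(batch, channels, length)``; convolutions are
stride-1 with same-padding; downsampling is max-pooling by 2; upsampling is
either non-learned nearest-neighbour repetition (V-Net path) or a learned
kernel-2 stride-2 transposed convolution (U-Net path).  Each layer caches
what its backward pass needs; ``backward`` must be called with the gradient
of the loss w.r.t. its own output and returns the gradient w.r.t. its input.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A named weight array with gradient buffer and trainability flag."""

    __slots__ = ("name", "value", "grad", "trainable")

    def __init__(self, name: str, value: np.ndarray, trainable: bool = True):
        self.name = name
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.trainable = trainable

    def zero_grad(self) -> None:
        self.grad = None

    def add_grad(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g


def fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int) -> np.ndarray:
    """Fan-in-scaled uniform initialization, U(-sqrt(6/fan_in), +)."""
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    """Base class; layers expose their parameters for optimization/freezing."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded stride-1 1-D convolution, optionally followed by ReLU."""

    is_conv = True

    def __init__(self, name: str, c_in: int, c_out: int, kernel: int = 3,
                 relu: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.name = name
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.relu = relu
        self.pad = (kernel - 1) // 2
        self.w = Param(f"{name}.w", fan_in_uniform(rng, (c_out, c_in * kernel),
                                                   c_in * kernel))
        self.b = Param(f"{name}.b", np.zeros(c_out))
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        k, p = self.kernel, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        # (n, c, L, k) -> (n*L, c*k)
        cols = sliding_window_view(xp, k, axis=2)
        cols = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(
            n * length, c * k)
        y = cols @ self.w.value.T + self.b.value
        y = y.reshape(n, length, self.c_out).transpose(0, 2, 1)
        mask = None
        if self.relu:
            mask = y > 0
            y = np.where(mask, y, 0.0)
        self._cache = (cols, x.shape, mask)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, mask = self._cache
        n, c, length = x_shape
        k, p = self.kernel, self.pad
        if mask is not None:
            dy = np.where(mask, dy, 0.0)
        dy2 = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(
            n * length, self.c_out)
        self.w.add_grad(dy2.T @ cols)
        self.b.add_grad(dy2.sum(axis=0))
        dcols = (dy2 @ self.w.value).reshape(n, length, c, k).transpose(0, 2, 1, 3)
        dxp = np.zeros((n, c, length + 2 * p), dtype=DTYPE)
        for j in range(k):
            dxp[:, :, j:j + length] += dcols[:, :, :, j]
        return dxp[:, :, p:p + length] if p else dxp


class ConvTranspose1d(Layer):
    """Kernel-2 stride-2 learned up-convolution (doubles the length)."""

    is_conv = True

    def __init__(self, name: str, c_in: int, c_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.name = name
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(f"{name}.w", fan_in_uniform(rng, (2, c_in, c_out), c_in))
        self.b = Param(f"{name}.b", np.zeros(c_out))
        self._cache: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        y = np.empty((n, self.c_out, 2 * length), dtype=DTYPE)
        xt = x.transpose(0, 2, 1)  # (n, L, c_in)
        for j in range(2):
            y[:, :, j::2] = (xt @ self.w.value[j]).transpose(0, 2, 1)
        y += self.b.value[None, :, None]
        self._cache = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        n, c, length = x.shape
        xt = x.transpose(0, 2, 1).reshape(n * length, c)
        dx = np.zeros_like(x)
        dw = np.empty_like(self.w.value)
        for j in range(2):
            dyj = np.ascontiguousarray(dy[:, :, j::2].transpose(0, 2, 1)).reshape(
                n * length, self.c_out)
            dw[j] = xt.T @ dyj
            dx += (dyj @ self.w.value[j].T).reshape(n, length, c).transpose(0, 2, 1)
        self.w.add_grad(dw)
        self.b.add_grad(dy.sum(axis=(0, 2)))
        return dx


class MaxPool1d(Layer):
    """Non-overlapping max-pooling by 2."""

    is_conv = False

    def __init__(self) -> None:
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        xr = x.reshape(n, c, length // 2, 2)
        idx = xr.argmax(axis=3)
        self._cache = (idx, x.shape)
        return np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, x_shape = self._cache
        n, c, length = x_shape
        dxr = np.zeros((n, c, length // 2, 2), dtype=DTYPE)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=3)
        return dxr.reshape(x_shape)


class Upsample1d(Layer):
    """Non-learned nearest-neighbour upsampling by 2."""

    is_conv = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(x, 2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, length = dy.shape
        return dy.reshape(n, c, length // 2, 2).sum(axis=3)


class Adam:
    """Adam optimizer over a fixed parameter list; frozen params are skipped
    entirely so their arrays stay bit-identical."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {id(p): np.zeros_like(p.value) for p in params if p.trainable}
        self.v = {id(p): np.zeros_like(p.value) for p in params if p.trainable}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p in self.params:
            if not p.trainable or p.grad is None:
                continue
            m = self.m[id(p)]
            v = self.v[id(p)]
            m += (1 - self.beta1) * (p.grad - m)
            v += (1 - self.beta2) * (p.grad**2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
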
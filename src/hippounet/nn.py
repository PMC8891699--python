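"""Minimal CPU neural-network engine (numpy) for the segmentation network.

Implements exactly the layers the encoder-decoder needs — same-padded
convolutions (2D/3D), batch normalization, leaky ReLU, and 2x max pooling
with index-preserving unpooling — each with an explicit hand-derived
backward pass.

Internally arrays are channel-first-of-all: ``(C, N, *spatial)``. Each
convolution is a single GEMM against a column matrix gathered by a compiled
kernel (see :mod:`hippounet.nn_kernels`); the backward pass runs as a
convolution of the output gradient with the flipped, transposed kernel, so
it reuses the same two primitives.

The engine is deterministic: no threading tricks, no random state of its own.
"""
from __future__ import annotations

import numpy as np

from . import nn_kernels as kernels
from .errors import ShapeError


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


class Conv:
    """Same-padded convolution, kernel ``k`` per spatial axis, with bias.

    Input/output layout: (C, N, *spatial).
    """

    def __init__(self, cin: int, cout: int, dim: int, k: int = 3, rng=None, name="conv",
                 dtype=np.float32, slope: float = 0.01):
        self.cin, self.cout, self.dim, self.k = cin, cout, dim, k
        fan_in = cin * k**dim
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / ((1.0 + slope**2) * fan_in))
        w = rng.normal(0.0, std, size=(cout, cin) + (k,) * dim).astype(dtype)
        self.weight = Param(f"{name}.weight", w)
        self.bias = Param(f"{name}.bias", np.zeros(cout, dtype=dtype))
        self._cache = None

    @property
    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        spatial = x.shape[2:]
        m = x.shape[1] * int(np.prod(spatial))
        wmat = self.weight.value.reshape(self.cout, -1)
        x = np.ascontiguousarray(x)
        if self.k == 1:
            y = wmat @ x.reshape(self.cin, m)
        else:
            y = wmat @ kernels.build_col(x, self.k)
        y += self.bias.value[:, None]
        if training:
            self._cache = x
        return y.reshape((self.cout, x.shape[1]) + spatial)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        m = x.size // self.cin
        dyf = np.ascontiguousarray(dy).reshape(self.cout, m)
        wmat = self.weight.value.reshape(self.cout, -1)
        self.bias.grad += dyf.sum(axis=1)
        if self.k == 1:
            self.weight.grad += (dyf @ x.reshape(self.cin, m).T).reshape(
                self.weight.value.shape
            )
            dx = wmat.T @ dyf
            self._cache = None
            return dx.reshape(x.shape)
        col = kernels.build_col(x, self.k)
        self.weight.grad += (dyf @ col.T).reshape(self.weight.value.shape)
        # dx = correlation of dy with the spatially flipped, transposed kernel
        wf = self.weight.value
        for ax in range(2, 2 + self.dim):
            wf = np.flip(wf, axis=ax)
        wf = np.ascontiguousarray(np.swapaxes(wf, 0, 1)).reshape(self.cin, -1)
        dy_col = kernels.build_col(dyf.reshape(dy.shape), self.k)
        dx = (wf @ dy_col).reshape(x.shape)
        self._cache = None
        return dx


class BatchNorm:
    """Per-channel batch normalization over batch and spatial axes."""

    def __init__(self, c: int, name="bn", momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32, eval_stats: str = "input"):
        self.c, self.momentum, self.eps = c, momentum, eps
        #: "input" normalizes inference batches with their own statistics
        #: (the statistics of the volume being segmented); "running" uses the
        #: exponential averages accumulated during training. Slice-wise
        #: training with batch size one makes the running averages a poor
        #: match for any particular volume, so "input" is the default.
        self.eval_stats = eval_stats
        self.gamma = Param(f"{name}.gamma", np.ones(c, dtype=dtype))
        self.beta = Param(f"{name}.beta", np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self._cache = None

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        xf = x.reshape(self.c, -1)
        if training or self.eval_stats == "input":
            mean = xf.mean(axis=1)
            var = xf.var(axis=1)
            if training:
                self.running_mean += self.momentum * (mean - self.running_mean)
                self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        sh = (self.c,) + (1,) * (x.ndim - 1)
        xhat = (x - mean.reshape(sh)) * inv.reshape(sh)
        if training:
            self._cache = (xhat, inv)
        return self.gamma.value.reshape(sh) * xhat + self.beta.value.reshape(sh)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = dy.size // self.c
        sh = (self.c,) + (1,) * (dy.ndim - 1)
        dgamma = (dy * xhat).reshape(self.c, -1).sum(axis=1)
        dbeta = dy.reshape(self.c, -1).sum(axis=1)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value.reshape(sh) * inv.reshape(sh)
        dx = g * (dy - (dbeta.reshape(sh) + xhat * dgamma.reshape(sh)) / m)
        self._cache = None
        return dx


class LeakyReLU:
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._cache = None

    params: list = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        # for slope < 1, max(x, slope*x) is exactly leaky ReLU
        y = np.maximum(x, self.slope * x)
        if training:
            self._cache = x < 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        neg = self._cache
        self._cache = None
        return np.where(neg, self.slope * dy, dy)


def _window_view(x: np.ndarray, dim: int):
    """(C, N, *sp) -> (C, N, *sp/2, 2**dim) grouping 2x windows."""
    c, n = x.shape[:2]
    sp = x.shape[2:]
    if any(s % 2 for s in sp):
        raise ShapeError(f"spatial shape {sp} not divisible by 2 for pooling")
    if dim == 2:
        h, w = sp
        v = x.reshape(c, n, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(v).reshape(c, n, h // 2, w // 2, 4)
    h, w, d = sp
    v = x.reshape(c, n, h // 2, 2, w // 2, 2, d // 2, 2).transpose(0, 1, 2, 4, 6, 3, 5, 7)
    return np.ascontiguousarray(v).reshape(c, n, h // 2, w // 2, d // 2, 8)


def _window_unview(v: np.ndarray, dim: int):
    c, n = v.shape[:2]
    if dim == 2:
        h2, w2 = v.shape[2:4]
        y = v.reshape(c, n, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(y).reshape(c, n, h2 * 2, w2 * 2)
    h2, w2, d2 = v.shape[2:5]
    y = v.reshape(c, n, h2, w2, d2, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
    return np.ascontiguousarray(y).reshape(c, n, h2 * 2, w2 * 2, d2 * 2)


def max_pool(x: np.ndarray, dim: int):
    """Factor-2 max pooling; returns (pooled, indices) with per-window argmax."""
    v = _window_view(x, dim)
    idx = v.argmax(axis=-1)
    pooled = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
    return pooled, idx


def max_unpool(y: np.ndarray, idx: np.ndarray, dim: int):
    """Place values at the recorded argmax positions, zeros elsewhere.

    ``y`` must have the same channel count as the tensor whose pooling
    produced ``idx`` (indices are per channel).
    """
    if y.shape != idx.shape:
        raise ShapeError(f"unpool input shape {y.shape} must match index shape {idx.shape}")
    nwin = 2**dim
    v = np.zeros(y.shape + (nwin,), dtype=y.dtype)
    np.put_along_axis(v, idx[..., None], y[..., None], axis=-1)
    return _window_unview(v, dim)


def pool_backward(dy_pooled: np.ndarray, idx: np.ndarray, dim: int):
    """Gradient of max_pool: scatter pooled gradients to argmax positions."""
    return max_unpool(dy_pooled, idx, dim)


def unpool_backward(dy_full: np.ndarray, idx: np.ndarray, dim: int):
    """Gradient of max_unpool: gather at the recorded positions."""
    v = _window_view(dy_full, dim)
    return np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]


def softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
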
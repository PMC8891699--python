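"""JIT-compiled memory primitives for the convolution engine.

Two operations dominate the engine's run time and are pure memory movement:
gathering the im2col-style column matrix (with implicit zero padding) and
its transpose used by the backward pass. Both are written as explicit loops
and compiled with numba; a numpy fallback keeps the package functional if
numba is unavailable.

Layouts: activations (C, N, *spatial); column matrix (C * K, N * prod(sp))
with row index c * K + offset, offsets in row-major kernel order.
"""
from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco


@njit(cache=True)
def _col2d(x, k, p, col):
    c_, n_, h_, w_ = x.shape
    for c in range(c_):
        for i in range(k):
            for j in range(k):
                row = c * k * k + i * k + j
                for n in range(n_):
                    base = n * h_ * w_
                    for a in range(h_):
                        sa = a + i - p
                        if sa < 0 or sa >= h_:
                            for b in range(w_):
                                col[row, base + a * w_ + b] = 0.0
                        else:
                            for b in range(w_):
                                sb = b + j - p
                                if sb < 0 or sb >= w_:
                                    col[row, base + a * w_ + b] = 0.0
                                else:
                                    col[row, base + a * w_ + b] = x[c, n, sa, sb]


@njit(cache=True)
def _colT2d(t, k, p, dx):
    """dx[c,n,a,b] = sum over offsets (i,j) of t[c*K+i*k+j, (n, a+p-i, b+p-j)]."""
    c_, n_, h_, w_ = dx.shape
    for c in range(c_):
        for n in range(n_):
            base = n * h_ * w_
            for a in range(h_):
                for b in range(w_):
                    acc = 0.0
                    for i in range(k):
                        sa = a + p - i
                        if sa < 0 or sa >= h_:
                            continue
                        for j in range(k):
                            sb = b + p - j
                            if sb < 0 or sb >= w_:
                                continue
                            acc += t[c * k * k + i * k + j, base + sa * w_ + sb]
                    dx[c, n, a, b] = acc


@njit(cache=True)
def _col3d(x, k, p, col):
    c_, n_, h_, w_, d_ = x.shape
    hw = h_ * w_ * d_
    for c in range(c_):
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    row = c * k * k * k + i * k * k + j * k + l
                    for n in range(n_):
                        base = n * hw
                        for a in range(h_):
                            sa = a + i - p
                            for b in range(w_):
                                sb = b + j - p
                                idx0 = base + (a * w_ + b) * d_
                                if sa < 0 or sa >= h_ or sb < 0 or sb >= w_:
                                    for e in range(d_):
                                        col[row, idx0 + e] = 0.0
                                else:
                                    for e in range(d_):
                                        se = e + l - p
                                        if se < 0 or se >= d_:
                                            col[row, idx0 + e] = 0.0
                                        else:
                                            col[row, idx0 + e] = x[c, n, sa, sb, se]


@njit(cache=True)
def _colT3d(t, k, p, dx):
    c_, n_, h_, w_, d_ = dx.shape
    hw = h_ * w_ * d_
    for c in range(c_):
        for n in range(n_):
            base = n * hw
            for a in range(h_):
                for b in range(w_):
                    for e in range(d_):
                        acc = 0.0
                        for i in range(k):
                            sa = a + p - i
                            if sa < 0 or sa >= h_:
                                continue
                            for j in range(k):
                                sb = b + p - j
                                if sb < 0 or sb >= w_:
                                    continue
                                for l in range(k):
                                    se = e + p - l
                                    if se < 0 or se >= d_:
                                        continue
                                    acc += t[
                                        c * k * k * k + i * k * k + j * k + l,
                                        base + (sa * w_ + sb) * d_ + se,
                                    ]
                        dx[c, n, a, b, e] = acc


def build_col(x: np.ndarray, k: int) -> np.ndarray:
    """Column matrix (cin*K, M) of ``x`` (C, N, *spatial), zero-padded."""
    dim = x.ndim - 2
    cin = x.shape[0]
    m = x.size // cin
    K = k**dim
    col = np.empty((cin * K, m), dtype=x.dtype)
    p = k // 2
    if dim == 2:
        _col2d(x, k, p, col)
    else:
        _col3d(x, k, p, col)
    return col


def col_transpose_accumulate(t: np.ndarray, k: int, shape) -> np.ndarray:
    """Adjoint of :func:`build_col`: fold a (cin*K, M) matrix back onto the
    input grid of ``shape`` = (C, N, *spatial)."""
    dim = len(shape) - 2
    dx = np.empty(shape, dtype=t.dtype)
    p = k // 2
    if dim == 2:
        _colT2d(t, k, p, dx)
    else:
        _colT3d(t, k, p, dx)
    return dx
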
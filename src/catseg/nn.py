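"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This module provides the small set of differentiable operations the
segmentation networks in this package are built from: N-dimensional
convolution (with stride, dilation and depthwise grouping), transposed
convolution, batch normalisation, 2x2 max pooling, nearest/linear factor-2
upsampling, the usual pointwise nonlinearities, and the softmax
cross-entropy / soft-Dice losses.  It is a deliberately small engine —
enough to express and train the two networks of the cascade on a CPU —
not a general deep-learning framework.

Gradients of every fused operation are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Sequence

import numpy as np

DTYPE = np.float32


# ---------------------------------------------------------------------------
# Tensor and graph machinery
# ---------------------------------------------------------------------------

class Tensor:
    """A node in the computation graph: a value, its gradient, and a
    backward closure mapping the output gradient to parent gradients."""

    __slots__ = ("data", "grad", "_parents", "_bwd")

    def __init__(self, data, parents=(), bwd=None):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = tuple(parents)
        self._bwd = bwd

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, leaf={self._bwd is None})"

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, _ensure(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, _ensure(other))

    def __rsub__(self, other):
        return sub(_ensure(other), self)

    def __mul__(self, other):
        return mul(self, _ensure(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _ensure(other))

    def __rtruediv__(self, other):
        return div(_ensure(other), self)

    def __neg__(self):
        return mul(self, _ensure(-1.0))

    def __getitem__(self, key):
        return slice_(self, key)

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad=None):
        """Backpropagate from this node (a scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._bwd is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._bwd(node.grad)):
                if g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE))


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# Pointwise / reduction ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data
    return Tensor(out, (a, b), lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = a.data - b.data
    return Tensor(out, (a, b), lambda g: (_unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)))


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data
    return Tensor(out, (a, b),
                  lambda g: (_unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)))


def div(a: Tensor, b: Tensor) -> Tensor:
    out = a.data / b.data
    return Tensor(out, (a, b),
                  lambda g: (_unbroadcast(g / b.data, a.shape),
                             _unbroadcast(-g * a.data / (b.data * b.data), b.shape)))


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(np.where(mask, x.data, 0), (x,), lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    return Tensor(s, (x,), lambda g: (g * s * (1.0 - s),))


def log(x: Tensor) -> Tensor:
    return Tensor(np.log(x.data), (x,), lambda g: (g / x.data,))


def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = x.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if axis is None:
            return (np.broadcast_to(g, x.shape).copy(),)
        axes = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, axes)
        return (np.broadcast_to(g, x.shape).copy(),)

    return Tensor(out, (x,), bwd)


def tmean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = x.data.size if axis is None else np.prod(
        [x.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
    return tsum(x, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def slice_(x: Tensor, key) -> Tensor:
    out = x.data[key]

    def bwd(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, key, g)
        return (gx,)

    return Tensor(out, (x,), bwd)


def concat(xs: Sequence[Tensor], axis: int = 1) -> Tensor:
    xs = list(xs)
    out = np.concatenate([x.data for x in xs], axis=axis)
    sizes = [x.shape[axis] for x in xs]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, tuple(xs), bwd)


# ---------------------------------------------------------------------------
# Convolution family
# ---------------------------------------------------------------------------

def _tuplify(v, nd: int) -> tuple:
    if isinstance(v, (tuple, list)):
        if len(v) != nd:
            raise ValueError(f"expected {nd} entries, got {v!r}")
        return tuple(int(i) for i in v)
    return (int(v),) * nd


try:  # numba accelerates the im2col/col2im data movement when available
    from numba import njit, prange
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

if _HAVE_NUMBA:
    @njit(parallel=True, cache=True, fastmath=True)
    def _im2col3d(xp, cols, s0, s1, s2, d0, d1, d2, k0, k1, k2, o0, o1, o2):
        n_batch, cin = xp.shape[0], xp.shape[1]
        for ni in prange(n_batch * o0):
            n = ni // o0
            i = ni % o0
            for j in range(o1):
                for k in range(o2):
                    col = 0
                    for c in range(cin):
                        for a in range(k0):
                            for b in range(k1):
                                for cc in range(k2):
                                    cols[n, i, j, k, col] = xp[
                                        n, c, i * s0 + a * d0,
                                        j * s1 + b * d1, k * s2 + cc * d2]
                                    col += 1

    @njit(parallel=True, cache=True, fastmath=True)
    def _col2im3d_s1(dcols, dxp, k0, k1, k2, o0, o1, o2):
        # stride-1 / dilation-1 fast path: loop bounds replace index checks
        n_batch, cin = dxp.shape[0], dxp.shape[1]
        p0, p1, p2 = dxp.shape[2], dxp.shape[3], dxp.shape[4]
        for nx in prange(n_batch * p0):
            n = nx // p0
            x = nx % p0
            a_lo = x - o0 + 1 if x - o0 + 1 > 0 else 0
            a_hi = x + 1 if x + 1 < k0 else k0
            for y in range(p1):
                b_lo = y - o1 + 1 if y - o1 + 1 > 0 else 0
                b_hi = y + 1 if y + 1 < k1 else k1
                for z in range(p2):
                    c_lo = z - o2 + 1 if z - o2 + 1 > 0 else 0
                    c_hi = z + 1 if z + 1 < k2 else k2
                    for c in range(cin):
                        acc = 0.0
                        for a in range(a_lo, a_hi):
                            for b in range(b_lo, b_hi):
                                for cc in range(c_lo, c_hi):
                                    acc += dcols[n, x - a, y - b, z - cc,
                                                 ((c * k0 + a) * k1 + b) * k2 + cc]
                        dxp[n, c, x, y, z] = acc

    @njit(parallel=True, cache=True, fastmath=True)
    def _col2im3d(dcols, dxp, s0, s1, s2, d0, d1, d2, k0, k1, k2, o0, o1, o2):
        n_batch, cin = dxp.shape[0], dxp.shape[1]
        p0, p1, p2 = dxp.shape[2], dxp.shape[3], dxp.shape[4]
        for nx in prange(n_batch * p0):
            n = nx // p0
            x = nx % p0
            for y in range(p1):
                for z in range(p2):
                    for c in range(cin):
                        acc = 0.0
                        for a in range(k0):
                            ia = x - a * d0
                            if ia < 0 or ia % s0 != 0:
                                continue
                            ia //= s0
                            if ia >= o0:
                                continue
                            for b in range(k1):
                                jb = y - b * d1
                                if jb < 0 or jb % s1 != 0:
                                    continue
                                jb //= s1
                                if jb >= o1:
                                    continue
                                for cc in range(k2):
                                    kc = z - cc * d2
                                    if kc < 0 or kc % s2 != 0:
                                        continue
                                    kc //= s2
                                    if kc >= o2:
                                        continue
                                    acc += dcols[n, ia, jb, kc,
                                                 ((c * k0 + a) * k1 + b) * k2 + cc]
                        dxp[n, c, x, y, z] = acc


def _im2col_numpy(xp, kernel, stride, dilation, out_sp):
    nd = len(kernel)
    sp_axes = tuple(range(2, 2 + nd))
    win_shape = tuple((kernel[i] - 1) * dilation[i] + 1 for i in range(nd))
    windows = np.lib.stride_tricks.sliding_window_view(xp, win_shape, axis=sp_axes)
    sel = (slice(None), slice(None)) \
        + tuple(slice(None, None, s) for s in stride) \
        + tuple(slice(None, None, d) for d in dilation)
    windows = windows[sel]  # (N, Cin, *out, *K)
    perm = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
    return np.ascontiguousarray(windows.transpose(perm))


def _col2im_numpy(dcols, xp_shape, kernel, stride, dilation, out_sp, dtype):
    nd = len(kernel)
    n_batch = xp_shape[0]
    cin = xp_shape[1]
    dxp = np.zeros(xp_shape, dtype=dtype)
    dcols = dcols.reshape((n_batch,) + out_sp + (cin,) + kernel)
    perm_b = (0, 1 + nd) + tuple(range(2 + nd, 2 + 2 * nd)) + tuple(range(1, 1 + nd))
    dcols = dcols.transpose(perm_b)  # (N, Cin, *K, *out)
    for off in itertools.product(*[range(k) for k in kernel]):
        sls = (slice(None), slice(None)) + tuple(
            slice(off[i] * dilation[i],
                  off[i] * dilation[i] + out_sp[i] * stride[i], stride[i])
            for i in range(nd))
        dxp[sls] += dcols[(slice(None), slice(None)) + off]
    return dxp


def _conv_out_len(n: int, k: int, s: int, p: int, d: int) -> int:
    eff = d * (k - 1) + 1
    out = (n + 2 * p - eff) // s + 1
    if out < 1:
        raise ValueError(
            f"convolution input of length {n} too small for kernel {k} "
            f"(dilation {d}, padding {p}, stride {s})")
    return out


def conv(x: Tensor, w: Tensor, stride=1, padding=0, dilation=1, groups: int = 1) -> Tensor:
    """N-D cross-correlation. ``x``: (N, Cin, *S); ``w``: (Cout, Cin/groups, *K).

    Supports ``groups == 1`` (dense) and ``groups == Cin`` with
    ``Cout == Cin`` (depthwise). The dense path lowers to a single GEMM via
    an im2col buffer (kept for the backward pass); the depthwise path loops
    over kernel offsets.
    """
    nd = w.data.ndim - 2
    stride, padding, dilation = (_tuplify(v, nd) for v in (stride, padding, dilation))
    xd, wd = x.data, w.data
    if xd.ndim != nd + 2:
        raise ValueError(f"expected {nd + 2}-D input, got {xd.ndim}-D")
    n_batch, cin = xd.shape[:2]
    cout = wd.shape[0]
    kernel = wd.shape[2:]
    if wd.shape[1] * groups != cin:
        raise ValueError(
            f"channel mismatch: layer expects {wd.shape[1] * groups} input "
            f"channels, got {cin}")
    if groups != 1 and not (groups == cin and cout == cin):
        raise ValueError("only dense (groups=1) or depthwise (groups=Cin) supported")
    pad_width = [(0, 0), (0, 0)] + [(p, p) for p in padding]
    xp = np.pad(xd, pad_width) if any(padding) else xd
    out_sp = tuple(_conv_out_len(xd.shape[2 + i], kernel[i], stride[i],
                                 padding[i], dilation[i]) for i in range(nd))
    offsets = list(itertools.product(*[range(k) for k in kernel]))

    def off_slices(off):
        return (slice(None), slice(None)) + tuple(
            slice(off[i] * dilation[i],
                  off[i] * dilation[i] + out_sp[i] * stride[i], stride[i])
            for i in range(nd))

    sp_axes = tuple(range(2, 2 + nd))
    prod_k = int(np.prod(kernel))
    # 2D inputs ride the 3D numba kernels through a free trailing axis
    k3 = kernel + (1,) * (3 - nd)
    s3 = stride + (1,) * (3 - nd)
    d3 = dilation + (1,) * (3 - nd)
    o3 = out_sp + (1,) * (3 - nd)
    stride_sel = (slice(None), slice(None)) + tuple(slice(None, None, s) for s in stride)
    if groups == 1:
        # im2col: windows -> (N * prod(out), Cin * prod(K)), then one GEMM
        ksize = cin * prod_k
        npos = n_batch * int(np.prod(out_sp))
        if prod_k == 1:
            cols = np.ascontiguousarray(
                np.moveaxis(xp[stride_sel], 1, -1)).reshape(npos, ksize)
        elif _HAVE_NUMBA:
            xp3 = xp.reshape(xp.shape + (1,) * (3 - nd))
            cols = np.empty((n_batch,) + o3 + (ksize,), dtype=xd.dtype)
            _im2col3d(xp3, cols, *s3, *d3, *k3, *o3)
            cols = cols.reshape(npos, ksize)
        else:
            cols = _im2col_numpy(xp, kernel, stride, dilation, out_sp).reshape(npos, ksize)
        w2 = wd.reshape(cout, ksize)
        out = (cols @ w2.T).reshape((n_batch,) + out_sp + (cout,))
        out = np.ascontiguousarray(np.moveaxis(out, -1, 1))
    else:
        out = np.zeros((n_batch, cout) + out_sp, dtype=xd.dtype)
        for off in offsets:
            view = xp[off_slices(off)]
            wk = wd[(slice(None), 0) + off].reshape((1, cout) + (1,) * nd)
            out += view * wk

    def bwd(g):
        dW = np.zeros_like(wd)
        if groups == 1:
            g2 = np.ascontiguousarray(np.moveaxis(g, 1, -1)).reshape(npos, cout)
            dW[...] = (g2.T @ cols).reshape(wd.shape)
            dcols = g2 @ w2
            if prod_k == 1:
                dxp = np.zeros_like(xp)
                dxp[stride_sel] = np.moveaxis(
                    dcols.reshape((n_batch,) + out_sp + (cin,)), -1, 1)
            elif _HAVE_NUMBA:
                dxp3 = np.empty(xp.shape + (1,) * (3 - nd), dtype=xd.dtype)
                dcols3 = dcols.reshape((n_batch,) + o3 + (ksize,))
                if s3 == (1, 1, 1) and d3 == (1, 1, 1):
                    _col2im3d_s1(dcols3, dxp3, *k3, *o3)
                else:
                    _col2im3d(dcols3, dxp3, *s3, *d3, *k3, *o3)
                dxp = dxp3.reshape(xp.shape)
            else:
                dxp = _col2im_numpy(dcols, xp.shape, kernel, stride, dilation,
                                    out_sp, xd.dtype)
        else:
            dxp = np.zeros_like(xp)
            for off in offsets:
                sls = off_slices(off)
                view = xp[sls]
                dW[(slice(None), 0) + off] += (g * view).sum(axis=(0, *sp_axes))
                wk = wd[(slice(None), 0) + off].reshape((1, cout) + (1,) * nd)
                dxp[sls] += g * wk
        if any(padding):
            core = (slice(None), slice(None)) + tuple(
                slice(p, xp.shape[2 + i] - p) for i, p in enumerate(padding))
            dx = dxp[core]
        else:
            dx = dxp
        return dx, dW

    return Tensor(out, (x, w), bwd)


def conv_transpose(x: Tensor, w: Tensor, stride) -> Tensor:
    """Transposed N-D convolution with kernel == stride (non-overlapping),
    i.e. learned factor-``stride`` upsampling. ``w``: (Cin, Cout, *K)."""
    nd = w.data.ndim - 2
    stride = _tuplify(stride, nd)
    xd, wd = x.data, w.data
    if wd.shape[2:] != stride:
        raise ValueError("conv_transpose requires kernel size == stride")
    n_batch, cin = xd.shape[:2]
    if wd.shape[0] != cin:
        raise ValueError(f"channel mismatch: layer expects {wd.shape[0]} input channels, got {cin}")
    cout = wd.shape[1]
    in_sp = xd.shape[2:]
    out_sp = tuple(in_sp[i] * stride[i] for i in range(nd))
    offsets = list(itertools.product(*[range(k) for k in stride]))
    sp_axes = tuple(range(2, 2 + nd))

    def off_slices(off):
        return (slice(None), slice(None)) + tuple(
            slice(off[i], off[i] + in_sp[i] * stride[i], stride[i]) for i in range(nd))

    out = np.zeros((n_batch, cout) + out_sp, dtype=xd.dtype)
    for off in offsets:
        wk = wd[(slice(None), slice(None)) + off]  # (Cin, Cout)
        contrib = np.tensordot(xd, wk, axes=([1], [0]))  # (N, *in, Cout)
        out[off_slices(off)] = np.moveaxis(contrib, -1, 1)

    def bwd(g):
        dx = np.zeros_like(xd)
        dW = np.zeros_like(wd)
        for off in offsets:
            gv = g[off_slices(off)]  # (N, Cout, *in)
            wk = wd[(slice(None), slice(None)) + off]
            dx += np.moveaxis(np.tensordot(gv, wk, axes=([1], [1])), -1, 1)
            dW[(slice(None), slice(None)) + off] += np.tensordot(
                xd, gv, axes=([0, *sp_axes], [0, *sp_axes]))
        return dx, dW

    return Tensor(out, (x, w), bwd)


# ---------------------------------------------------------------------------
# Pooling and resampling
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2, on (N, C, H, W); odd trailing rows/cols
    are dropped (floor semantics)."""
    n, c, h, w = x.shape
    h2, w2 = h // 2 * 2, w // 2 * 2
    xc = x.data[:, :, :h2, :w2]
    win = xc.reshape(n, c, h2 // 2, 2, w2 // 2, 2).transpose(0, 1, 2, 4, 3, 5) \
            .reshape(n, c, h2 // 2, w2 // 2, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gw = np.zeros((n, c, h2 // 2, w2 // 2, 4), dtype=g.dtype)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(x.data)
        gx[:, :, :h2, :w2] = gw.reshape(n, c, h2 // 2, w2 // 2, 2, 2) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2)
        return (gx,)

    return Tensor(out, (x,), bwd)


def upsample_nearest2x(x: Tensor, axes: Sequence[int]) -> Tensor:
    out = x.data
    for ax in axes:
        out = np.repeat(out, 2, axis=ax)

    def bwd(g):
        for ax in reversed(list(axes)):
            shp = list(g.shape)
            shp[ax] //= 2
            g = g.reshape(shp[:ax] + [shp[ax], 2] + shp[ax + 1:]).sum(axis=ax + 1)
        return (g,)

    return Tensor(out, (x,), bwd)


def _lin2_matrix(n: int, dtype) -> np.ndarray:
    """Factor-2 linear interpolation matrix (2n x n), edges clamped
    (half-pixel / align_corners=False sampling)."""
    m = np.zeros((2 * n, n), dtype=dtype)
    for i in range(n):
        m[2 * i, i] += 0.75
        m[2 * i, max(i - 1, 0)] += 0.25
        m[2 * i + 1, i] += 0.75
        m[2 * i + 1, min(i + 1, n - 1)] += 0.25
    return m


def upsample_linear2x(x: Tensor, axes: Sequence[int]) -> Tensor:
    """Bi/trilinear factor-2 upsampling along ``axes``."""
    axes = list(axes)
    mats = {}
    out = x.data
    for ax in axes:
        m = _lin2_matrix(out.shape[ax], out.dtype)
        mats[ax] = m
        out = np.moveaxis(np.moveaxis(out, ax, -1) @ m.T, -1, ax)

    def bwd(g):
        for ax in reversed(axes):
            g = np.moveaxis(np.moveaxis(g, ax, -1) @ mats[ax], -1, ax)
        return (np.ascontiguousarray(g),)

    return Tensor(np.ascontiguousarray(out), (x,), bwd)


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Channel-wise batch normalisation (channel axis 1). Running statistics
    are updated in place during training and used verbatim at evaluation."""
    axes = (0,) + tuple(range(2, x.ndim))
    c = x.shape[1]
    shape = (1, c) + (1,) * (x.ndim - 2)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean += momentum * (mu - running_mean)
        running_var += momentum * (var - running_var)
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    mu_r, inv_r = mu.reshape(shape), inv.reshape(shape)
    xhat = (x.data - mu_r) * inv_r
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

    def bwd(g):
        dbeta = g.sum(axis=axes)
        dgamma = (g * xhat).sum(axis=axes)
        dxhat = g * gamma.data.reshape(shape)
        if training:
            dx = inv_r * (dxhat - dxhat.mean(axis=axes, keepdims=True)
                          - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True))
        else:
            dx = dxhat * inv_r
        return dx, dgamma, dbeta

    return Tensor(out, (x, gamma, beta), bwd)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        return (p * (g - (g * p).sum(axis=axis, keepdims=True)),)

    return Tensor(p, (x,), bwd)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean voxelwise softmax cross-entropy. ``logits``: (N, C, *S);
    ``labels``: integer array (N, *S)."""
    ld = logits.data
    z = ld - ld.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))  # (N, *S)
    lab = labels[:, None, ...]
    true_logit = np.take_along_axis(z, lab, axis=1)[:, 0]
    count = lse.size
    loss = (lse - true_logit).sum() / count

    def bwd(g):
        p = np.exp(z - lse[:, None, ...])
        np.put_along_axis(p, lab, np.take_along_axis(p, lab, axis=1) - 1.0, axis=1)
        return (g * p / count,)

    return Tensor(np.asarray(loss, dtype=ld.dtype), (logits,), bwd)


def one_hot(labels: np.ndarray, n_classes: int, dtype=DTYPE) -> np.ndarray:
    """(N, *S) integer labels -> (N, C, *S) one-hot array."""
    out = np.zeros((labels.shape[0], n_classes) + labels.shape[1:], dtype=dtype)
    np.put_along_axis(out, labels[:, None, ...], 1.0, axis=1)
    return out


def soft_dice_loss(logits: Tensor, labels: np.ndarray, n_classes: int,
                   foreground_only: bool = True, eps: float = 1e-6) -> Tensor:
    """1 - mean soft Dice over classes (foreground classes by default)."""
    p = softmax(logits, axis=1)
    g = one_hot(labels, n_classes, dtype=logits.data.dtype)
    axes = (0,) + tuple(range(2, logits.ndim))
    inter = tsum(mul(p, Tensor(g)), axis=axes)           # (C,)
    denom = tsum(p, axis=axes) + Tensor(g.sum(axis=axes))
    dice = (2.0 * inter + eps) / (denom + eps)
    if foreground_only:
        dice = dice[1:]
    return 1.0 - tmean(dice)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(DTYPE)


class Module:
    """Base class: parameter/buffer discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True
        self._buffer_names: list[str] = []

    def register_buffer(self, name: str, arr: np.ndarray):
        setattr(self, name, arr)
        self._buffer_names.append(name)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name in self._buffer_names:
            yield prefix + name, getattr(self, name)
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        d.update({"buffer:" + name: b.copy() for name, b in self.named_buffers()})
        return d

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, arr in state.items():
            if key.startswith("buffer:"):
                tgt = buffers[key[len("buffer:"):]]
                tgt[...] = arr
            else:
                params[key].data = np.array(arr, dtype=params[key].data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError


def count_parameters(module: Module | None) -> int:
    """Exact count of trainable scalars in a module (0 for empty containers)."""
    if module is None:
        return 0
    return int(sum(p.data.size for p in module.parameters()))


class Conv(Module):
    """N-D convolution layer; kernel length fixes the dimensionality."""

    def __init__(self, in_channels: int, out_channels: int, kernel,
                 rng: np.random.Generator, stride=1, padding=0, dilation=1,
                 groups: int = 1, bias: bool = True):
        super().__init__()
        kernel = kernel if isinstance(kernel, (tuple, list)) else (kernel,)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        fan_in = (in_channels // groups) * int(np.prod(kernel))
        self.weight = Parameter(he_normal(
            rng, (out_channels, in_channels // groups) + tuple(kernel), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = conv(x, self.weight, self.stride, self.padding, self.dilation, self.groups)
        if self.bias is not None:
            y = y + self.bias.data.reshape((1, -1) + (1,) * (y.ndim - 2))
        return y


class ConvTranspose(Module):
    """Learned factor-``stride`` upsampling (transposed conv, kernel == stride)."""

    def __init__(self, in_channels: int, out_channels: int, stride,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        stride = tuple(stride) if isinstance(stride, (tuple, list)) else (stride,)
        fan_in = in_channels * int(np.prod(stride))
        self.stride = stride
        self.weight = Parameter(he_normal(
            rng, (in_channels, out_channels) + stride, fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = conv_transpose(x, self.weight, self.stride)
        if self.bias is not None:
            y = y + self.bias.data.reshape((1, -1) + (1,) * (y.ndim - 2))
        return y


class BatchNorm(Module):
    def __init__(self, num_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_channels, dtype=DTYPE))
        self.beta = Parameter(np.zeros(num_channels, dtype=DTYPE))
        self.momentum, self.eps = momentum, eps
        self.register_buffer("running_mean", np.zeros(num_channels, dtype=DTYPE))
        self.register_buffer("running_var", np.ones(num_channels, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm(x, self.gamma, self.beta, self.running_mean,
                          self.running_var, self.training, self.momentum, self.eps)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Adam with decoupled-from-graph L2 weight decay added to the raw gradient."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self._t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1 ** self._t)
            vhat = self._v[i] / (1 - self.b2 ** self._t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
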
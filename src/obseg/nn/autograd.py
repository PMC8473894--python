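"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation networks in this package are small 2D fully convolutional
networks that must train on a single CPU in minutes, so instead of a deep
learning framework the handful of primitives they need — same-padded
convolution, batch normalisation, PReLU, 2x2 max-pooling with stored indices,
softmax, batched matrix products for the attention layer — are implemented
directly on float32 numpy arrays with hand-written backward passes.

A :class:`Tensor` wraps an ndarray; operations record a backward closure only
while gradients are enabled (see :class:`no_grad`) and at least one operand
requires them, so inference carries no graph overhead.  All backward passes
are validated against central finite differences in the test-suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        # float64 is honoured only for explicit float64 arrays (useful for
        # finite-difference gradient checks); everything else, including
        # Python scalars, becomes float32 so graphs never silently upcast
        if isinstance(data, (np.ndarray, np.generic)) and data.dtype == np.float64:
            arr = np.asarray(data)
        else:
            arr = np.asarray(data)
            if arr.dtype != np.float32:
                arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, neg(_as_tensor(other)))

    def __rsub__(self, other):
        return add(_as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, e):
        return power(self, e)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def swapaxes(self, a, b):
        return swapaxes(self, a, b)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t: Tensor, g: np.ndarray):
    if t.requires_grad:
        t.grad = g if t.grad is None else t.grad + g


def _make(data: np.ndarray, parents, backward) -> Tensor:
    need = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    out = Tensor(data)
    if need:
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _make(out, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    def backward(g):
        _accumulate(a, -g)

    return _make(-a.data, (a,), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    out = a.data / b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g / b.data, a.data.shape))
        _accumulate(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _make(out, (a, b), backward)


def power(a: Tensor, e: float) -> Tensor:
    out = a.data ** e

    def backward(g):
        _accumulate(a, g * e * a.data ** (e - 1.0))

    return _make(out, (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g):
        _accumulate(a, g / a.data)

    return _make(np.log(a.data), (a,), backward)


def exp(a: Tensor) -> Tensor:
    out = np.exp(a.data)

    def backward(g):
        _accumulate(a, g * out)

    return _make(out, (a,), backward)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    out = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        _accumulate(a, g * mask)

    return _make(out, (a,), backward)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Element-wise maximum; on ties the gradient routes to ``a``."""
    take_a = a.data >= b.data
    out = np.where(take_a, a.data, b.data)

    def backward(g):
        _accumulate(a, _unbroadcast(g * take_a, a.data.shape))
        _accumulate(b, _unbroadcast(g * ~take_a, b.data.shape))

    return _make(out, (a, b), backward)


# ---------------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            _accumulate(a, np.broadcast_to(g, a.data.shape).copy())
            return
        axes = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, axes)
        _accumulate(a, np.broadcast_to(g, a.data.shape).copy())

    return _make(out, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def reshape(a: Tensor, shape) -> Tensor:
    def backward(g):
        _accumulate(a, g.reshape(a.data.shape))

    return _make(a.data.reshape(shape), (a,), backward)


def swapaxes(a: Tensor, ax1: int, ax2: int) -> Tensor:
    def backward(g):
        _accumulate(a, g.swapaxes(ax1, ax2))

    return _make(a.data.swapaxes(ax1, ax2), (a,), backward)


def pad2d(a: Tensor, pads) -> Tensor:
    """Zero-pad the trailing two axes; ``pads`` = ((top, bottom), (left, right))."""
    (t, b), (l, r) = pads
    width = [(0, 0)] * (a.ndim - 2) + [(t, b), (l, r)]
    H, W = a.data.shape[-2:]

    def backward(g):
        sl = (Ellipsis, slice(t, t + H), slice(l, l + W))
        _accumulate(a, g[sl])

    return _make(np.pad(a.data, width), (a,), backward)


def crop2d(a: Tensor, pads) -> Tensor:
    """Inverse of :func:`pad2d`: remove margins from the trailing two axes."""
    (t, b), (l, r) = pads
    H, W = a.data.shape[-2:]
    sl = (Ellipsis, slice(t, H - b), slice(l, W - r))

    def backward(g):
        width = [(0, 0)] * (a.ndim - 2) + [(t, b), (l, r)]
        _accumulate(a, np.pad(g, width))

    return _make(a.data[sl], (a,), backward)


# ---------------------------------------------------------------------------
# linear algebra / nonlinearity
# ---------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = np.matmul(a.data, b.data)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        _accumulate(a, _unbroadcast(ga, a.data.shape))
        _accumulate(b, _unbroadcast(gb, b.data.shape))

    return _make(out, (a, b), backward)


def softmax(a: Tensor, axis: int) -> Tensor:
    # allocation-lean: one temporary for arrays that can reach N^2 elements
    m = a.data.max(axis=axis, keepdims=True)
    s = np.subtract(a.data, m)
    np.exp(s, out=s)
    s /= s.sum(axis=axis, keepdims=True)

    def backward(g):
        t = g * s
        dot = t.sum(axis=axis, keepdims=True)
        np.subtract(g, dot, out=t)
        t *= s
        _accumulate(a, t)

    return _make(s, (a,), backward)


def prelu(x: Tensor, a: Tensor) -> Tensor:
    """Parametric ReLU with per-channel slope ``a`` of shape (C, 1, 1)."""
    pos = x.data > 0
    out = np.where(pos, x.data, a.data * x.data)

    def backward(g):
        if a.requires_grad:
            ga = (g * np.where(pos, 0.0, x.data)).sum(axis=(0, 2, 3))
            _accumulate(a, ga.reshape(a.data.shape))
        if x.requires_grad:
            _accumulate(x, g * np.where(pos, 1.0, a.data))

    return _make(out, (x, a), backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: int):
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # B,C,H,W,k,k
    B, C, H, W = win.shape[:4]
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
        B, C * k * k, H * W)
    return cols, H, W


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded 2D convolution (odd kernel), NCHW layout, stride 1."""
    F, C, k, _ = w.data.shape
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    cols, H, W = _im2col(xp, k)
    B = x.data.shape[0]
    out = np.matmul(w.data.reshape(F, -1), cols) + b.data.reshape(1, F, 1)
    out = out.reshape(B, F, H, W)

    def backward(g):
        gf = g.reshape(B, F, H * W)
        if b.requires_grad:
            _accumulate(b, g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.matmul(gf, cols.transpose(0, 2, 1)).sum(axis=0)
            _accumulate(w, gw.reshape(w.data.shape))
        if x.requires_grad:
            gcols = np.matmul(w.data.reshape(F, -1).T, gf)  # B, C*k*k, N
            gcols = gcols.reshape(B, C, k, k, H, W)
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    gxp[:, :, i:i + H, j:j + W] += gcols[:, :, i, j]
            _accumulate(x, gxp[:, :, p:p + H, p:p + W])

    return _make(out, (x, w, b), backward)


# ---------------------------------------------------------------------------
# batch normalisation
# ---------------------------------------------------------------------------

def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
                 running_var: np.ndarray, training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    xd = x.data
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        m = xd.shape[0] * xd.shape[2] * xd.shape[3]
        unbiased = var * (m / max(m - 1, 1))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mu = running_mean
        var = running_var
    std = np.sqrt(var + eps).astype(xd.dtype)
    xhat = (xd - mu.astype(xd.dtype)[None, :, None, None]) / std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if beta.requires_grad:
            _accumulate(beta, g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            _accumulate(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx_hat = g * gamma.data[None, :, None, None]
            if training:
                gi = (gx_hat
                      - gx_hat.mean(axis=(0, 2, 3), keepdims=True)
                      - xhat * (gx_hat * xhat).mean(axis=(0, 2, 3), keepdims=True))
                _accumulate(x, gi / std[None, :, None, None])
            else:
                _accumulate(x, gx_hat / std[None, :, None, None])

    return _make(out, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# index-preserving pooling
# ---------------------------------------------------------------------------

def max_pool2x2(x: Tensor):
    """2x2/stride-2 max pooling; returns (pooled, indices) with the argmax
    position inside each window retained for exact unpooling."""
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("max_pool2x2 requires even spatial dimensions")
    r = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = np.ascontiguousarray(r).reshape(B, C, H // 2, W // 2, 4)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            gr = np.zeros((B, C, H // 2, W // 2, 4), dtype=g.dtype)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gx = gr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            _accumulate(x, np.ascontiguousarray(gx).reshape(B, C, H, W))

    return _make(out, (x,), backward), idx


def max_unpool2x2(y: Tensor, idx: np.ndarray) -> Tensor:
    """Place each pooled value back at its stored window position, zeros elsewhere."""
    B, C, H2, W2 = y.data.shape
    r = np.zeros((B, C, H2, W2, 4), dtype=y.data.dtype)
    np.put_along_axis(r, idx[..., None], y.data[..., None], axis=-1)
    out = r.reshape(B, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    out = np.ascontiguousarray(out).reshape(B, C, H2 * 2, W2 * 2)

    def backward(g):
        if y.requires_grad:
            gr = g.reshape(B, C, H2, 2, W2, 2).transpose(0, 1, 2, 4, 3, 5)
            gr = np.ascontiguousarray(gr).reshape(B, C, H2, W2, 4)
            _accumulate(y, np.take_along_axis(gr, idx[..., None], axis=-1)[..., 0])

    return _make(out, (y,), backward)
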
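"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains small 3D convolutional networks on CPU; this module
provides the tensor/graph machinery they need and nothing more: broadcasted
elementwise arithmetic, (batched) matmul, reductions, shape ops, zero-padded
slicing, a 3D convolution primitive (dense and depthwise) and axis-wise
linear resampling.  Gradients are accumulated by topological traversal of
the recorded graph.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (forward passes only, e.g. evaluation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._vjps: tuple[Callable[[np.ndarray], np.ndarray], ...] = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- graph ---------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for parent, vjp in zip(node._parents, node._vjps):
                pg = vjp(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if len(axes) > 1 else axes[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], vjps: Sequence[Callable]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED:
        tracked = [(p, v) for p, v in zip(parents, vjps)
                   if p.requires_grad or p._parents]
        if tracked:
            out._parents = tuple(p for p, _ in tracked)
            out._vjps = tuple(v for _, v in tracked)
            out.requires_grad = True
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- elementwise -------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data + b.data, (a, b),
                 (lambda g: _unbroadcast(g, a.shape),
                  lambda g: _unbroadcast(g, b.shape)))


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data * b.data, (a, b),
                 (lambda g: _unbroadcast(g * b.data, a.shape),
                  lambda g: _unbroadcast(g * a.data, b.shape)))


def power(a, p):
    a = as_tensor(a)
    p = float(p)
    out = a.data ** p
    return _make(out, (a,), (lambda g: g * p * a.data ** (p - 1.0),))


def exp(a):
    a = as_tensor(a)
    out = np.exp(a.data)
    return _make(out, (a,), (lambda g: g * out,))


def log(a):
    a = as_tensor(a)
    return _make(np.log(a.data), (a,), (lambda g: g / a.data,))


def sqrt(a):
    a = as_tensor(a)
    out = np.sqrt(a.data)
    return _make(out, (a,), (lambda g: g * 0.5 / out,))


def tanh(a):
    a = as_tensor(a)
    out = np.tanh(a.data)
    return _make(out, (a,), (lambda g: g * (1.0 - out * out),))


def sigmoid(a):
    a = as_tensor(a)
    out = _expit(a.data)
    return _make(out, (a,), (lambda g: g * out * (1.0 - out),))


def _expit(x):
    # overflow-safe logistic
    out = np.empty_like(x, dtype=np.result_type(x, np.float32))
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out.astype(x.dtype) if np.issubdtype(x.dtype, np.floating) else out


def relu(a):
    a = as_tensor(a)
    mask = a.data > 0
    return _make(np.where(mask, a.data, 0.0).astype(a.dtype), (a,),
                 (lambda g: g * mask,))


def softplus(a):
    a = as_tensor(a)
    out = np.logaddexp(0.0, a.data)
    sig = _expit(a.data)
    return _make(out.astype(a.dtype), (a,), (lambda g: g * sig,))


def tabs(a):
    a = as_tensor(a)
    s = np.sign(a.data)
    return _make(np.abs(a.data), (a,), (lambda g: g * s,))


# -- reductions --------------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return np.broadcast_to(g, a.shape).astype(a.dtype)
        ax = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, ax)
        return np.broadcast_to(g, a.shape).astype(a.dtype)

    return _make(out, (a,), (vjp,))


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    if axis is None:
        n = a.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[i] for i in ax]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


# -- shape ops ---------------------------------------------------------------

def reshape(a, shape):
    a = as_tensor(a)
    return _make(a.data.reshape(shape), (a,), (lambda g: g.reshape(a.shape),))


def transpose(a, axes):
    a = as_tensor(a)
    inv = np.argsort(axes)
    return _make(a.data.transpose(axes), (a,), (lambda g: g.transpose(inv),))


def swap_last2(a):
    a = as_tensor(a)
    return _make(np.swapaxes(a.data, -1, -2), (a,),
                 (lambda g: np.swapaxes(g, -1, -2),))


def concat(tensors, axis=0):
    ts = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            return g[tuple(sl)]
        return vjp

    return _make(data, ts, tuple(make_vjp(i) for i in range(len(ts))))


def pad(a, pad_width):
    """Zero padding; ``pad_width`` follows np.pad convention."""
    a = as_tensor(a)
    data = np.pad(a.data, pad_width)

    def vjp(g):
        sl = tuple(slice(lo, g.shape[i] - hi) for i, (lo, hi) in enumerate(pad_width))
        return g[sl]

    return _make(data, (a,), (vjp,))


def getitem(a, idx):
    a = as_tensor(a)
    data = a.data[idx]

    def vjp(g):
        out = np.zeros(a.shape, dtype=g.dtype)
        np.add.at(out, idx, g)
        return out

    return _make(data, (a,), (vjp,))


# -- linear algebra ----------------------------------------------------------

def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = np.matmul(a.data, b.data)

    def vjp_a(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        return _unbroadcast(ga, a.shape) if ga.shape != a.shape else ga

    def vjp_b(g):
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return _unbroadcast(gb, b.shape) if gb.shape != b.shape else gb

    return _make(out, (a, b), (vjp_a, vjp_b))


def axis_dot(a, m: np.ndarray, axis: int):
    """Contract axis ``axis`` of ``a`` with the columns of constant matrix
    ``m`` (shape (out, in)); the result keeps the axis in place.

    Used for (adaptive) average pooling and linear interpolation, which are
    constant row-stochastic linear maps along one spatial axis.
    """
    a = as_tensor(a)
    data = np.moveaxis(np.tensordot(a.data, m, axes=([axis], [1])), -1, axis)

    def vjp(g):
        return np.moveaxis(np.tensordot(g, m, axes=([axis], [0])), -1, axis).astype(a.dtype)

    return _make(data, (a,), (vjp,))


# -- composite helpers -------------------------------------------------------

def softmax(a, axis=-1):
    a = as_tensor(a)
    shift = a - Tensor(np.max(a.data, axis=axis, keepdims=True))
    e = exp(shift)
    return e / tsum(e, axis=axis, keepdims=True)


def log_softmax(a, axis=-1):
    a = as_tensor(a)
    shift = a - Tensor(np.max(a.data, axis=axis, keepdims=True))
    return shift - log(tsum(exp(shift), axis=axis, keepdims=True))


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under ``logits`` (B, K)."""
    labels = np.asarray(labels)
    n, k = logits.shape
    onehot = np.zeros((n, k), dtype=logits.dtype)
    onehot[np.arange(n), labels] = 1.0
    return -tsum(Tensor(onehot) * log_softmax(logits, axis=1)) / n


# -- convolution primitives --------------------------------------------------

def conv3d(x, w, b=None, stride: int = 1, padding: int = 0):
    """Dense 3D convolution.

    x: (B, C, D, H, W); w: (O, C, k, k, k); b: (O,) or None.
    """
    x, w = as_tensor(x), as_tensor(w)
    B, C, D, H, W = x.shape
    O, Cw, k, _, _ = w.shape
    if C != Cw:
        raise ValueError(f"conv3d channel mismatch: input has {C}, weight expects {Cw}")
    p, s = padding, stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
    Do, Ho, Wo = win.shape[2:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(B * Do * Ho * Wo, C * k ** 3)
    out = (cols @ w.data.reshape(O, -1).T).reshape(B, Do, Ho, Wo, O).transpose(0, 4, 1, 2, 3)

    def vjp_x(g):
        gcols = g.transpose(0, 2, 3, 4, 1).reshape(-1, O) @ w.data.reshape(O, -1)
        gwin = gcols.reshape(B, Do, Ho, Wo, C, k, k, k)
        gxp = np.zeros_like(xp)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    gxp[:, :, dz:dz + Do * s:s, dy:dy + Ho * s:s, dx:dx + Wo * s:s] += (
                        gwin[..., dz, dy, dx].transpose(0, 4, 1, 2, 3))
        return gxp[:, :, p:p + D, p:p + H, p:p + W]

    def vjp_w(g):
        gw = g.transpose(0, 2, 3, 4, 1).reshape(-1, O).T @ cols
        return gw.reshape(w.shape)

    out_t = _make(out, (x, w), (vjp_x, vjp_w))
    if b is not None:
        out_t = out_t + reshape(as_tensor(b), (1, O, 1, 1, 1))
    return out_t


def depthwise_conv3d(x, w, b=None, stride: int = 1, padding: int = 0):
    """Per-channel 3D convolution; w: (C, k, k, k)."""
    x, w = as_tensor(x), as_tensor(w)
    B, C, D, H, W = x.shape
    Cw, k, _, _ = w.shape
    if C != Cw:
        raise ValueError(f"depthwise_conv3d channel mismatch: {C} vs {Cw}")
    p, s = padding, stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
    Do, Ho, Wo = win.shape[2:5]
    wk = w.data.reshape(C, -1)
    out = np.einsum("bcpqrk,ck->bcpqr", win.reshape(B, C, Do, Ho, Wo, -1), wk)

    def vjp_x(g):
        gxp = np.zeros_like(xp)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    gxp[:, :, dz:dz + Do * s:s, dy:dy + Ho * s:s, dx:dx + Wo * s:s] += (
                        g * w.data[None, :, dz, dy, dx, None, None, None])
        return gxp[:, :, p:p + D, p:p + H, p:p + W]

    def vjp_w(g):
        gw = np.einsum("bcpqr,bcpqrk->ck", g, win.reshape(B, C, Do, Ho, Wo, -1))
        return gw.reshape(w.shape)

    out_t = _make(out, (x, w), (vjp_x, vjp_w))
    if b is not None:
        out_t = out_t + reshape(as_tensor(b), (1, C, 1, 1, 1))
    return out_t


# -- resampling matrices -----------------------------------------------------

def pool_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic adaptive average-pooling matrix (n_out, n_in).

    Bin edges follow the floor/ceil convention, so n_out == n_in gives the
    identity and n_out > n_in duplicates (overlapping bins).
    """
    m = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo = (i * n_in) // n_out
        hi = -(-((i + 1) * n_in) // n_out)  # ceil
        m[i, lo:hi] = 1.0 / (hi - lo)
    return m


def interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Linear interpolation matrix (n_out, n_in), rows convex (sum to 1)."""
    m = np.zeros((n_out, n_in))
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    # align-corners sampling: endpoints map to endpoints
    pos = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    for i in range(n_out):
        m[i, lo[i]] += 1.0 - frac[i]
        m[i, hi[i]] += frac[i]
    return m


def adaptive_avg_pool3d(x, out_size):
    """Adaptive average pooling of (B, C, D, H, W) to spatial ``out_size``."""
    x = as_tensor(x)
    od, oh, ow = out_size
    d, h, w = x.shape[2:]
    y = x
    if d != od:
        y = axis_dot(y, pool_matrix(d, od).astype(x.dtype), axis=2)
    if h != oh:
        y = axis_dot(y, pool_matrix(h, oh).astype(x.dtype), axis=3)
    if w != ow:
        y = axis_dot(y, pool_matrix(w, ow).astype(x.dtype), axis=4)
    return y


def interpolate3d(x, out_size):
    """Trilinear resize of (B, C, D, H, W) to spatial ``out_size``."""
    x = as_tensor(x)
    od, oh, ow = out_size
    d, h, w = x.shape[2:]
    y = x
    if d != od:
        y = axis_dot(y, interp_matrix(d, od).astype(x.dtype), axis=2)
    if h != oh:
        y = axis_dot(y, interp_matrix(h, oh).astype(x.dtype), axis=3)
    if w != ow:
        y = axis_dot(y, interp_matrix(w, ow).astype(x.dtype), axis=4)
    return y
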
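"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the compute core of the package: a small define-by-run tape with the
handful of primitives the recognition network needs (broadcast arithmetic,
matmul, 3x3/1x1 convolution via im2col, bilinear resampling, reductions,
sigmoid/ReLU, log-softmax cross-entropy). Arrays follow the NCHW layout.

Every primitive's backward pass is exercised against central finite
differences in the test suite; nothing here is specific to the pest model.
"""

from __future__ import annotations

import numpy as np

from .resample import bilinear_matrix

__all__ = [
    "Tensor",
    "add", "mul", "sub", "div", "matmul", "power",
    "relu", "sigmoid", "exp", "log", "tanh",
    "tsum", "tmean", "reshape", "transpose", "concat",
    "conv2d", "bilinear_resize", "global_avg_pool",
    "log_softmax", "softmax_cross_entropy", "softmax",
    "bilinear_matrix",
]


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __neg__(self):
        return mul(self, _wrap(np.array(-1.0, dtype=self.data.dtype)))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __pow__(self, p):
        return power(self, p)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad=None):
        """Run reverse-mode accumulation from this tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        return self


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _accumulate(t: Tensor, g: np.ndarray):
    if not (t.requires_grad or t._prev):
        return
    if t.grad is None:
        t.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient g down to `shape` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._prev for p in parents):
        out._prev = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    data = a.data - b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(-g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    data = a.data / b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g / b.data, a.data.shape))
        _accumulate(b, _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return _make(data, (a, b), backward)


def power(a: Tensor, p: float) -> Tensor:
    data = a.data ** p

    def backward(g):
        _accumulate(a, g * p * a.data ** (p - 1))

    return _make(data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def backward(g):
        _accumulate(a, g @ b.data.T)
        _accumulate(b, a.data.T @ g)

    return _make(data, (a, b), backward)


# ---------------------------------------------------------------------------
# elementwise nonlinearities
# ---------------------------------------------------------------------------

def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    data = a.data * mask

    def backward(g):
        _accumulate(a, g * mask)

    return _make(data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accumulate(a, g * data * (1.0 - data))

    return _make(data, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    data = np.tanh(a.data)

    def backward(g):
        _accumulate(a, g * (1.0 - data ** 2))

    return _make(data, (a,), backward)


def exp(a: Tensor) -> Tensor:
    data = np.exp(a.data)

    def backward(g):
        _accumulate(a, g * data)

    return _make(data, (a,), backward)


def log(a: Tensor) -> Tensor:
    data = np.log(a.data)

    def backward(g):
        _accumulate(a, g / a.data)

    return _make(data, (a,), backward)


# ---------------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % a.data.ndim for ax in axes)
            shape = [1 if i in axes else s for i, s in enumerate(a.data.shape)]
            g = g.reshape(shape)
        _accumulate(a, np.broadcast_to(g, a.data.shape).astype(a.data.dtype))

    return _make(data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape
    data = a.data.reshape(shape)

    def backward(g):
        _accumulate(a, g.reshape(old))

    return _make(data, (a,), backward)


def transpose(a: Tensor, axes) -> Tensor:
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        _accumulate(a, g.transpose(inv))

    return _make(data, (a,), backward)


def concat(tensors, axis: int) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accumulate(t, g[tuple(idx)])

    return _make(data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# convolution (im2col) and resampling
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                      # (n,c,oh,ow,kh,kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(gcols, x_shape, kh, kw, stride, pad):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    g = gcols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    gx = np.zeros((n, c, hp, wp), dtype=gcols.dtype)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += g[:, :, i, j]
    if pad:
        gx = gx[:, :, pad:hp - pad, pad:wp - pad]
    return gx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW; w is (Cout, Cin, kh, kw)."""
    cout, cin, kh, kw = w.data.shape
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    wflat = w.data.reshape(cout, cin * kh * kw)
    out = cols @ wflat.T
    if b is not None:
        out = out + b.data
    n = x.data.shape[0]
    data = out.reshape(n, oh, ow, cout).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gflat = g.transpose(0, 2, 3, 1).reshape(-1, cout)
        _accumulate(w, (gflat.T @ cols).reshape(w.data.shape))
        if b is not None:
            _accumulate(b, gflat.sum(axis=0))
        gcols = gflat @ wflat
        _accumulate(x, _col2im(gcols, x.data.shape, kh, kw, stride, pad))

    return _make(data, parents, backward)


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resample of the spatial dims of an NCHW tensor."""
    _, _, h, w = x.data.shape
    ah = bilinear_matrix(h, out_h, dtype=x.data.dtype)
    aw = bilinear_matrix(w, out_w, dtype=x.data.dtype)
    data = np.einsum("ph,nchw,qw->ncpq", ah, x.data, aw, optimize=True)

    def backward(g):
        _accumulate(x, np.einsum("ph,ncpq,qw->nchw", ah, g, aw, optimize=True))

    return _make(data, (x,), backward)


def global_avg_pool(x: Tensor, keepdims: bool = False) -> Tensor:
    """Spatial mean of an NCHW tensor -> (N, C) or (N, C, 1, 1)."""
    return tmean(x, axis=(2, 3), keepdims=keepdims)


# ---------------------------------------------------------------------------
# classification losses
# ---------------------------------------------------------------------------

def log_softmax(a: Tensor) -> Tensor:
    m = a.data.max(axis=-1, keepdims=True)
    z = a.data - m
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    data = z - lse
    p = np.exp(data)

    def backward(g):
        _accumulate(a, g - p * g.sum(axis=-1, keepdims=True))

    return _make(data, (a,), backward)


def softmax(a: Tensor) -> Tensor:
    return exp(log_softmax(a))


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy between softmax(logits) and integer labels."""
    labels = np.asarray(labels)
    n = logits.data.shape[0]
    ls = log_softmax(logits)
    picked = ls.data[np.arange(n), labels]
    data = np.array(-picked.mean(), dtype=logits.data.dtype)

    def backward(g):
        gl = np.zeros_like(ls.data)
        gl[np.arange(n), labels] = -g / n
        _accumulate(ls, gl)

    return _make(data, (ls,), backward)
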
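"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operator set needed by a small anchor-free convolutional
detector: 2-D convolution (grouped/depthwise included), batch normalisation
(training and inference statistics), 5x5 stride-1 max pooling, nearest-neighbour
2x upsampling, channel concatenation/slicing, the SiLU/ReLU/sigmoid/softmax
nonlinearities and elementwise arithmetic with NumPy broadcasting.

All data is float32.  Gradients are accumulated into ``Tensor.grad`` by
``Tensor.backward()`` via a topological sweep.  Graph recording can be switched
off globally (``no_grad``) for inference, in which case the ops degenerate to
plain NumPy calls at negligible overhead.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph recording."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


class Tensor:
    """An ndarray plus an optional backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = _as_array(data)
        self.requires_grad = requires_grad and _grad_enabled
        self.grad: np.ndarray | None = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers -------------------------------------------------
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

    # -- autograd engine ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # -- operator sugar -------------------------------------------------------
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

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / float(other))

    def __neg__(self):
        return mul(self, -1.0)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _make(data, parents: Iterable[Tensor], backward) -> Tensor:
    req = _grad_enabled and any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=tuple(parents), backward=backward)


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), bw)


def power(a, p: float) -> Tensor:
    a = _wrap(a)
    out_data = np.power(a.data, p)

    def bw(g):
        if a.requires_grad:
            a._accum(g * p * np.power(a.data, p - 1.0))

    return _make(out_data, (a,), bw)


def exp(a) -> Tensor:
    a = _wrap(a)
    out_data = np.exp(a.data)

    def bw(g):
        if a.requires_grad:
            a._accum(g * out_data)

    return _make(out_data, (a,), bw)


def log(a, eps: float = 1e-12) -> Tensor:
    a = _wrap(a)
    out_data = np.log(np.maximum(a.data, eps))

    def bw(g):
        if a.requires_grad:
            a._accum(g / np.maximum(a.data, eps))

    return _make(out_data, (a,), bw)


def sqrt(a, eps: float = 1e-12) -> Tensor:
    a = _wrap(a)
    out_data = np.sqrt(np.maximum(a.data, 0.0))

    def bw(g):
        if a.requires_grad:
            a._accum(g * 0.5 / np.maximum(out_data, eps))

    return _make(out_data, (a,), bw)


def arctan(a) -> Tensor:
    a = _wrap(a)
    out_data = np.arctan(a.data)

    def bw(g):
        if a.requires_grad:
            a._accum(g / (1.0 + a.data * a.data))

    return _make(out_data, (a,), bw)


def clamp(a, lo=None, hi=None) -> Tensor:
    a = _wrap(a)
    out_data = np.clip(a.data, lo, hi)
    mask = np.ones_like(a.data)
    if lo is not None:
        mask = mask * (a.data >= lo)
    if hi is not None:
        mask = mask * (a.data <= hi)

    def bw(g):
        if a.requires_grad:
            a._accum(g * mask)

    return _make(out_data, (a,), bw)


def maximum(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = np.maximum(a.data, b.data)
    amask = (a.data >= b.data).astype(np.float32)

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * amask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (1.0 - amask), b.data.shape))

    return _make(out_data, (a, b), bw)


def minimum(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = np.minimum(a.data, b.data)
    amask = (a.data <= b.data).astype(np.float32)

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * amask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (1.0 - amask), b.data.shape))

    return _make(out_data, (a, b), bw)


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    out_data = a.data.reshape(shape)

    def bw(g):
        if a.requires_grad:
            a._accum(g.reshape(a.data.shape))

    return _make(out_data, (a,), bw)


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    out_data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def bw(g):
        if a.requires_grad:
            a._accum(np.transpose(g, inv))

    return _make(out_data, (a,), bw)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return _make(out_data, tensors, bw)


def narrow(a, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice along one axis (differentiable)."""
    a = _wrap(a)
    idx = [slice(None)] * a.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    out_data = a.data[idx]

    def bw(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[idx] = g
            a._accum(full)

    return _make(out_data, (a,), bw)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if a.requires_grad:
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).astype(np.float32))

    return _make(out_data, (a,), bw)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


# ---------------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------------

def relu(a) -> Tensor:
    a = _wrap(a)
    out_data = np.maximum(a.data, 0.0)
    mask = (a.data > 0.0).astype(np.float32)

    def bw(g):
        if a.requires_grad:
            a._accum(g * mask)

    return _make(out_data, (a,), bw)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))

    def bw(g):
        if a.requires_grad:
            a._accum(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), bw)


def silu(a) -> Tensor:
    """SiLU(x) = x * sigmoid(x)."""
    a = _wrap(a)
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))
    out_data = a.data * s

    def bw(g):
        if a.requires_grad:
            a._accum(g * (s * (1.0 + a.data * (1.0 - s))))

    return _make(out_data, (a,), bw)


def softmax(a, axis: int) -> Tensor:
    a = _wrap(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accum(out_data * (g - dot))

    return _make(out_data, (a,), bw)


# ---------------------------------------------------------------------------
# convolution via im2col
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(B,C,H,W) -> (B, C, k*k, L) patch matrix."""
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    cols = np.empty((b, c, k * k, oh * ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            patch = x[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
            cols[:, :, i * k + j, :] = patch.reshape(b, c, -1)
    return cols, oh, ow


def _col2im(cols: np.ndarray, xshape, k: int, stride: int, pad: int,
            oh: int, ow: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patches back into the image."""
    b, c, h, w = xshape
    xp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(b, c, k * k, oh, ow)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += \
                cols[:, :, i * k + j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


def conv2d(x, weight, bias=None, stride: int = 1, padding: int | None = None,
           groups: int = 1) -> Tensor:
    """2-D convolution.  weight: (Cout, Cin/groups, k, k); padding defaults to k//2."""
    x, weight = _wrap(x), _wrap(weight)
    if bias is not None:
        bias = _wrap(bias)
    cout, cing, k, _ = weight.data.shape
    pad = k // 2 if padding is None else padding
    b, cin, h, w = x.data.shape
    if cin != cing * groups:
        raise ValueError(
            f"conv2d channel mismatch: input has {cin} channels, "
            f"weight expects {cing * groups} (groups={groups})")
    cols, oh, ow = _im2col(x.data, k, stride, pad)  # (B, Cin, k2, L)
    if groups == 1:
        cols2 = cols.reshape(b, cin * k * k, oh * ow)
        wf = weight.data.reshape(cout, cin * k * k)
        out = np.matmul(wf, cols2)  # (B, Cout, L)
    elif groups == cin and cing == 1:  # depthwise
        wf = weight.data.reshape(cout, k * k)
        out = np.einsum("bckl,ck->bcl", cols, wf)
        cols2 = cols
    else:
        cpg_in, cpg_out = cin // groups, cout // groups
        cols2 = cols.reshape(b, groups, cpg_in * k * k, oh * ow)
        wf = weight.data.reshape(groups, cpg_out, cpg_in * k * k)
        out = np.einsum("gok,bgkl->bgol", wf, cols2).reshape(b, cout, oh * ow)
    if bias is not None:
        out = out + bias.data[None, :, None]
    out = out.reshape(b, cout, oh, ow)

    def bw(g):
        gf = g.reshape(b, cout, oh * ow)
        if bias is not None and bias.requires_grad:
            bias._accum(gf.sum(axis=(0, 2)))
        if groups == 1:
            wf_ = weight.data.reshape(cout, cin * k * k)
            if weight.requires_grad:
                gw = np.einsum("bol,bkl->ok", gf, cols2)
                weight._accum(gw.reshape(weight.data.shape))
            if x.requires_grad:
                gcols = np.einsum("ok,bol->bkl", wf_, gf)
                x._accum(_col2im(gcols.reshape(b, cin, k * k, oh * ow),
                                 x.data.shape, k, stride, pad, oh, ow))
        elif groups == cin and cing == 1:
            wf_ = weight.data.reshape(cout, k * k)
            if weight.requires_grad:
                gw = np.einsum("bcl,bckl->ck", gf, cols2)
                weight._accum(gw.reshape(weight.data.shape))
            if x.requires_grad:
                gcols = np.einsum("ck,bcl->bckl", wf_, gf)
                x._accum(_col2im(gcols, x.data.shape, k, stride, pad, oh, ow))
        else:
            cpg_in, cpg_out = cin // groups, cout // groups
            gfg = gf.reshape(b, groups, cpg_out, oh * ow)
            wf_ = weight.data.reshape(groups, cpg_out, cpg_in * k * k)
            if weight.requires_grad:
                gw = np.einsum("bgol,bgkl->gok", gfg, cols2)
                weight._accum(gw.reshape(weight.data.shape))
            if x.requires_grad:
                gcols = np.einsum("gok,bgol->bgkl", wf_, gfg)
                x._accum(_col2im(gcols.reshape(b, cin, k * k, oh * ow),
                                 x.data.shape, k, stride, pad, oh, ow))

    parents = (x, weight) + ((bias,) if bias is not None else ())
    return _make(out, parents, bw)


def max_pool2d(x, k: int = 5, stride: int = 1, padding: int | None = None) -> Tensor:
    x = _wrap(x)
    pad = k // 2 if padding is None else padding
    b, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                constant_values=-np.inf)
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    out = np.full((b, c, oh, ow), -np.inf, dtype=np.float32)
    arg = np.zeros((b, c, oh, ow), dtype=np.int16)
    for i in range(k):
        for j in range(k):
            patch = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
            sel = patch > out
            out[sel] = patch[sel]
            arg[sel] = i * k + j

    def bw(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                mask = arg == (i * k + j)
                gx[:, :, i:i + stride * oh:stride,
                   j:j + stride * ow:stride] += g * mask
        if pad:
            gx = gx[:, :, pad:-pad, pad:-pad]
        x._accum(gx)

    return _make(out, (x,), bw)


def upsample_nearest2x(x) -> Tensor:
    x = _wrap(x)
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        if x.requires_grad:
            b, c, h2, w2 = g.shape
            x._accum(g.reshape(b, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return _make(out_data, (x,), bw)


def batch_norm(x, gamma, beta, running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.03, eps: float = 1e-3) -> Tensor:
    """Batch normalisation over (B,H,W) per channel.

    In training mode uses batch statistics and updates the running buffers
    in place; in eval mode uses the running buffers (affine transform only).
    """
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    if training:
        axes = (0, 2, 3)
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        n = x.data.size / x.data.shape[1]
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mean
        running_var *= (1.0 - momentum)
        running_var += momentum * var * (n / max(n - 1.0, 1.0))
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
            if training:
                n = x.data.size / x.data.shape[1]
                gxh = g * gamma.data[None, :, None, None]
                t1 = gxh - gxh.mean(axis=(0, 2, 3), keepdims=True)
                t2 = xhat * (gxh * xhat).mean(axis=(0, 2, 3), keepdims=True)
                x._accum(inv_std[None, :, None, None] * (t1 - t2))
            else:
                x._accum(g * gs)

    return _make(out_data, (x, gamma, beta), bw)
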
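"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This engine exists to train the invertible volumetric flow in this package:
it implements exactly the operators the flow and its coupling networks need
(elementwise arithmetic, tanh/exp/log, reductions, a channel-last linear map,
3D convolution with same-padding, and sign-less log-determinant), each with an
analytic vector-Jacobian product.  Gradients are accumulated into ``Parameter``
leaves by :meth:`Tensor.backward` over a topologically sorted tape.

The design follows the classic define-by-run pattern: every operator returns a
new :class:`Tensor` holding its value and a closure that propagates the output
gradient to its parents.  A ``no_grad`` context skips tape construction for
pure inference (decoding, sampling, data augmentation).
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    """Disable gradient-tape construction inside the block."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A value in the computation graph."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data)
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad = None

    # -- graph -------------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g), self.data.shape)
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # -- operator sugar ----------------------------------------------------
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
        return mul(self, reciprocal(as_tensor(other)))

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.array(data), requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data, parents, backward):
    if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


# ---------------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad)
        if b.requires_grad:
            b._accumulate(out.grad)

    out = _make(a.data + b.data, (a, b), backward)
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward():
        if a.requires_grad:
            a._accumulate(out.grad * b.data)
        if b.requires_grad:
            b._accumulate(out.grad * a.data)

    out = _make(out_data, (a, b), backward)
    return out


def reciprocal(a) -> Tensor:
    a = as_tensor(a)
    out_data = 1.0 / a.data

    def backward():
        a._accumulate(-out.grad * out_data * out_data)

    out = _make(out_data, (a,), backward)
    return out


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward():
        a._accumulate(out.grad * out_data)

    out = _make(out_data, (a,), backward)
    return out


def log(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(a.data)

    def backward():
        a._accumulate(out.grad / a.data)

    out = _make(out_data, (a,), backward)
    return out


def log_abs(a) -> Tensor:
    """log|a|, gradient 1/a (valid for a != 0)."""
    a = as_tensor(a)
    out_data = np.log(np.abs(a.data))

    def backward():
        a._accumulate(out.grad / a.data)

    out = _make(out_data, (a,), backward)
    return out


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def backward():
        a._accumulate(out.grad * (1.0 - out_data * out_data))

    out = _make(out_data, (a,), backward)
    return out


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def backward():
        a._accumulate(out.grad * mask)

    out = _make(a.data * mask, (a,), backward)
    return out


def square(a) -> Tensor:
    return mul(a, a)


# ---------------------------------------------------------------------------
# reductions / shape ops
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward():
        g = out.grad
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, [ax % a.data.ndim for ax in axes])
        a._accumulate(np.broadcast_to(g, a.data.shape))

    out = _make(out_data, (a,), backward)
    return out


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)

    def backward():
        a._accumulate(out.grad.reshape(a.data.shape))

    out = _make(a.data.reshape(shape), (a,), backward)
    return out


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    inv = np.argsort(axes)

    def backward():
        a._accumulate(out.grad.transpose(inv))

    out = _make(a.data.transpose(axes), (a,), backward)
    return out


def narrow(a, start: int, stop: int) -> Tensor:
    """Slice the last (channel) axis: ``a[..., start:stop]``."""
    a = as_tensor(a)

    def backward():
        g = np.zeros_like(a.data)
        g[..., start:stop] = out.grad
        a._accumulate(g)

    out = _make(a.data[..., start:stop], (a,), backward)
    return out


def concat(parts, axis: int = -1) -> Tensor:
    parts = [as_tensor(p) for p in parts]
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def backward():
        g = np.moveaxis(out.grad, axis, -1)
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                p._accumulate(np.moveaxis(g[..., lo:hi], -1, axis))

    out = _make(np.concatenate([p.data for p in parts], axis=axis), tuple(parts), backward)
    return out


# ---------------------------------------------------------------------------
# linear algebra / convolution
# ---------------------------------------------------------------------------

def linear(x, w) -> Tensor:
    """Channel-mixing map ``y[..., j] = sum_i x[..., i] w[i, j]``."""
    x, w = as_tensor(x), as_tensor(w)
    out_data = x.data @ w.data

    def backward():
        if x.requires_grad:
            x._accumulate(out.grad @ w.data.T)
        if w.requires_grad:
            nbatch = tuple(range(x.data.ndim - 1))
            w._accumulate(np.tensordot(x.data, out.grad, axes=(nbatch, nbatch)))

    out = _make(out_data, (x, w), backward)
    return out


def conv3d(x, w, b=None) -> Tensor:
    """3D convolution, channel-last, stride 1, zero same-padding, odd kernel.

    ``x``: (N, W, H, D, Cin); ``w``: (k, k, k, Cin, Cout); ``b``: (Cout,).
    """
    x, w = as_tensor(x), as_tensor(w)
    b = as_tensor(b) if b is not None else None
    k = w.data.shape[0]
    pad = k // 2
    n, wd, ht, dp, _ = x.data.shape
    co = w.data.shape[-1]
    xp = np.pad(x.data, ((0, 0),) + ((pad, pad),) * 3 + ((0, 0),)) if pad else x.data
    out_data = np.zeros((n, wd, ht, dp, co), dtype=x.data.dtype)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                out_data += xp[:, i:i + wd, j:j + ht, l:l + dp, :] @ w.data[i, j, l]
    if b is not None:
        out_data += b.data

    def backward():
        g = out.grad
        if x.requires_grad:
            gxp = np.zeros_like(xp)
        if w.requires_grad:
            gw = np.zeros_like(w.data)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    patch = xp[:, i:i + wd, j:j + ht, l:l + dp, :]
                    if w.requires_grad:
                        gw[i, j, l] = np.tensordot(
                            patch, g, axes=((0, 1, 2, 3), (0, 1, 2, 3)))
                    if x.requires_grad:
                        gxp[:, i:i + wd, j:j + ht, l:l + dp, :] += g @ w.data[i, j, l].T
        if w.requires_grad:
            w._accumulate(gw)
        if x.requires_grad:
            x._accumulate(gxp[:, pad:pad + wd, pad:pad + ht, pad:pad + dp, :] if pad else gxp)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_data, parents, backward)
    return out


def slogdet_abs(w) -> Tensor:
    """log|det W| for a square matrix; gradient is ``inv(W).T``."""
    w = as_tensor(w)
    sign, logdet = np.linalg.slogdet(w.data)
    if sign == 0:
        raise np.linalg.LinAlgError("singular weight matrix")

    def backward():
        w._accumulate(out.grad * np.linalg.inv(w.data).T)

    out = _make(np.asarray(logdet, dtype=w.data.dtype), (w,), backward)
    return out


# ---------------------------------------------------------------------------
# module container
# ---------------------------------------------------------------------------

class Module:
    """Base class providing recursive parameter discovery."""

    def parameters(self):
        params = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Parameter):
                        params.append(item)
                    elif isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None
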
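"""Minimal reverse-mode automatic differentiation over numpy arrays.

The segmentation generator, the multiscale discriminator and every
differentiable loss in this package are built from the ops below. The engine
is deliberately small: float32 values, a flat tape built by construction,
and an iterative topological backward pass. Shapes follow the convention
(N, C, X, Y, Z) inside networks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "constant", "parameter", "add", "sub", "mul", "div", "neg",
    "tsum", "tmean", "relu", "leaky_relu", "sigmoid", "softmax_channel",
    "tabs", "concat_channels", "scale", "minimum",
]


class Tensor:
    """A node in the computation graph.

    ``value`` is a numpy float32 array (scalars are 0-d arrays); ``grad``
    accumulates d(loss)/d(self) during :meth:`backward`.
    """

    __slots__ = ("value", "grad", "parents", "bwd", "requires_grad")

    def __init__(self, value, parents=(), bwd=None, requires_grad=False):
        arr = np.asarray(value)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.value = arr
        self.grad = None
        self.parents = parents
        self.bwd = bwd
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.value.shape

    def item(self):
        return float(self.value)

    def _accumulate(self, g):
        g = np.asarray(g, dtype=self.value.dtype).reshape(self.value.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self):
        if self.value.ndim != 0:
            raise ValueError("backward() requires a scalar loss tensor")
        order = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones((), dtype=self.value.dtype)
        for node in reversed(order):
            if node.bwd is not None and node.grad is not None:
                node.bwd(node.grad)

    # convenience arithmetic on graph nodes
    def __add__(self, other):
        return add(self, _wrap(other))

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __neg__(self):
        return neg(self)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(value):
    """A graph leaf that never receives gradient."""
    return Tensor(value)


def parameter(value):
    """A trainable graph leaf."""
    return Tensor(value, requires_grad=True)


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a, b):
    out_val = a.value + b.value

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return Tensor(out_val, (a, b), bwd)


def sub(a, b):
    out_val = a.value - b.value

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.shape))

    return Tensor(out_val, (a, b), bwd)


def mul(a, b):
    out_val = a.value * b.value

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.value, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.value, b.shape))

    return Tensor(out_val, (a, b), bwd)


def div(a, b):
    out_val = a.value / b.value

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.value, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.value / (b.value ** 2), b.shape))

    return Tensor(out_val, (a, b), bwd)


def neg(a):
    def bwd(g):
        if a.requires_grad:
            a._accumulate(-g)

    return Tensor(-a.value, (a,), bwd)


def scale(a, s: float):
    s = np.float32(s)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * s)

    return Tensor(a.value * s, (a,), bwd)


def tsum(a, axis=None):
    out_val = a.value.sum(axis=axis)

    def bwd(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape))
        else:
            g_exp = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g_exp, a.shape))

    return Tensor(out_val, (a,), bwd)


def tmean(a, axis=None):
    n = a.value.size if axis is None else a.value.shape[axis]
    return scale(tsum(a, axis=axis), 1.0 / n)


def relu(a):
    mask = a.value > 0

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return Tensor(a.value * mask, (a,), bwd)


def leaky_relu(a, alpha=0.2):
    pos = a.value > 0
    mult = np.where(pos, np.float32(1.0), np.float32(alpha))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * mult)

    return Tensor(a.value * mult, (a,), bwd)


def sigmoid(a):
    out_val = 1.0 / (1.0 + np.exp(-a.value))

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * out_val * (1.0 - out_val))

    return Tensor(out_val, (a,), bwd)


def minimum(a, b):
    """Elementwise minimum; gradient routed to the smaller input (ties: a)."""
    take_a = a.value <= b.value
    out_val = np.where(take_a, a.value, b.value)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(np.where(take_a, g, 0), a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(np.where(take_a, 0, g), b.shape))

    return Tensor(out_val, (a, b), bwd)


def tabs(a):
    sign = np.sign(a.value)

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g * sign)

    return Tensor(np.abs(a.value), (a,), bwd)


def softmax_channel(a, axis=1):
    """Softmax along the channel axis of an (N, C, ...) tensor."""
    shifted = a.value - a.value.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_val = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        if a.requires_grad:
            dot = (g * out_val).sum(axis=axis, keepdims=True)
            a._accumulate(out_val * (g - dot))

    return Tensor(out_val, (a,), bwd)


def concat_channels(tensors):
    """Concatenate (N, C, X, Y, Z) tensors along the channel axis."""
    vals = [t.value for t in tensors]
    out_val = np.concatenate(vals, axis=1)
    sizes = [v.shape[1] for v in vals]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accumulate(g[:, lo:hi])

    return Tensor(out_val, tuple(tensors), bwd)
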
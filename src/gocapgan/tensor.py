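"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports higher-order derivatives: every vector-Jacobian product is itself
expressed in :class:`Tensor` operations, so differentiating through a
gradient (as the Wasserstein gradient penalty requires) needs no special
machinery — calling :func:`grad` on the output of another :func:`grad` just
works.

All arrays are float64. The op set is deliberately small: elementwise
arithmetic, exp/log/sqrt/power, broadcast-aware matmul, reshape/transpose,
axis sums and gather/scatter along one axis (the primitive behind padded
1-D convolution via im2col).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "constant", "parameter", "grad", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference-only passes)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _to_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjps")

    def __init__(self, data, requires_grad=False, parents=(), vjps=()):
        self.data = _to_array(data)
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._vjps = vjps

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in _axes_tuple(axis, self.data.ndim)]
        )
        return tsum(self, axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    return Tensor(x, requires_grad=False)


def parameter(x) -> Tensor:
    return Tensor(x, requires_grad=True)


def _axes_tuple(axis, ndim):
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        return (axis % ndim,)
    return tuple(a % ndim for a in axis)


def _make(data, parents, vjps):
    if not _GRAD_ENABLED or not any(p.requires_grad for p in parents):
        return Tensor(data)
    return Tensor(data, requires_grad=True, parents=parents, vjps=vjps)


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Sum `g` down to `shape` (the adjoint of NumPy broadcasting)."""
    if g.data.shape == tuple(shape):
        return g
    ndim_extra = g.data.ndim - len(shape)
    if ndim_extra > 0:
        g = tsum(g, axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.data.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.data.shape != tuple(shape):
        g = reshape(g, tuple(shape))
    return g


# -- primitive ops ------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data
    return _make(
        out,
        (a, b),
        (lambda g: _unbroadcast(g, a.data.shape), lambda g: _unbroadcast(g, b.data.shape)),
    )


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data
    return _make(
        out,
        (a, b),
        (
            lambda g: _unbroadcast(mul(g, b), a.data.shape),
            lambda g: _unbroadcast(mul(g, a), b.data.shape),
        ),
    )


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    exponent = float(exponent)
    out = a.data ** exponent
    return _make(out, (a,), (lambda g: mul(g, mul(power(a, exponent - 1.0), exponent)),))


def exp(a) -> Tensor:
    a = as_tensor(a)
    # backward recomputes exp(a) rather than closing over the output tensor:
    # a self-reference would create an uncollectable-by-refcount cycle that
    # pins large graphs in memory during training
    return _make(np.exp(a.data), (a,), (lambda g: mul(g, exp(a)),))


def log(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.log(a.data), (a,), (lambda g: mul(g, power(a, -1.0)),))


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data

    def vjp_a(g):
        ga = matmul(g, transpose_last2(b))
        return _unbroadcast_matmul(ga, a.data.shape)

    def vjp_b(g):
        gb = matmul(transpose_last2(a), g)
        return _unbroadcast_matmul(gb, b.data.shape)

    return _make(out, (a, b), (vjp_a, vjp_b))


def transpose_last2(a: Tensor) -> Tensor:
    axes = list(range(a.data.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return transpose(a, tuple(axes))


def _unbroadcast_matmul(g: Tensor, shape) -> Tensor:
    if g.data.shape == tuple(shape):
        return g
    ndim_extra = g.data.ndim - len(shape)
    if ndim_extra > 0:
        g = tsum(g, axis=tuple(range(ndim_extra)))
    axes = tuple(
        i for i in range(len(shape) - 2) if shape[i] == 1 and g.data.shape[i] != 1
    )
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    axes = _axes_tuple(axis, a.data.ndim)
    out = a.data.sum(axis=axes, keepdims=keepdims)

    def vjp(g):
        if not keepdims:
            kshape = list(a.data.shape)
            for ax in axes:
                kshape[ax] = 1
            g = reshape(g, tuple(kshape))
        return broadcast_to(g, a.data.shape)

    return _make(out, (a,), (vjp,))


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    out = np.broadcast_to(a.data, shape)  # read-only view; downstream ops only read
    return _make(out, (a,), (lambda g: _unbroadcast(g, a.data.shape),))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return _make(
        a.data.reshape(shape), (a,), (lambda g: reshape(g, a.data.shape),)
    )


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    inv = tuple(np.argsort(axes))
    return _make(np.transpose(a.data, axes), (a,), (lambda g: transpose(g, inv),))


def take(a, indices, axis: int) -> Tensor:
    """Gather along one axis with an integer index array (adjoint: scatter-add)."""
    a = as_tensor(a)
    idx = np.asarray(indices, dtype=np.intp)
    out = np.take(a.data, idx, axis=axis)
    return _make(
        out, (a,), (lambda g: scatter_add(g, idx, axis, a.data.shape[axis]),)
    )


def scatter_add(g, indices, axis: int, length: int) -> Tensor:
    """Adjoint of :func:`take`: sum gradient slices back to their source index."""
    g = as_tensor(g)
    idx = np.asarray(indices, dtype=np.intp)
    shape = list(g.data.shape)
    shape[axis] = length
    out = np.zeros(shape, dtype=np.float64)
    sl = [slice(None)] * len(shape)
    sl[axis] = idx
    np.add.at(out, tuple(sl), g.data)
    return _make(out, (g,), (lambda gg: take(gg, idx, axis),))


# -- composed ops used throughout the package --------------------------------


def leaky_relu(a, negative_slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    slope_mask = np.where(a.data > 0.0, 1.0, negative_slope)
    return mul(a, constant(slope_mask))


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    # exp of the negated absolute value is always <= 1: numerically safe
    neg = constant(np.where(a.data >= 0, -1.0, 1.0))
    e = exp(mul(a, neg))  # exp(-|a|)
    pos = constant((a.data >= 0).astype(np.float64))
    # a>=0: 1/(1+e)      a<0: e/(1+e)
    denom = power(add(1.0, e), -1.0)
    return add(mul(pos, denom), mul(1.0 - pos.data, mul(e, denom)))


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shift = constant(a.data.max(axis=axis, keepdims=True))
    e = exp(a - shift)
    return mul(e, power(tsum(e, axis=axis, keepdims=True), -1.0))


# -- backward pass ------------------------------------------------------------


def _toposort(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    return order  # postorder: dependencies first; backward walks it reversed


def grad(output: Tensor, wrt, grad_output=None):
    """Gradients of a scalar (or seeded) output with respect to `wrt` tensors.

    Returns a list of Tensors aligned with `wrt`; each is itself part of the
    graph, so the result can be differentiated again.
    """
    wrt = list(wrt)
    if grad_output is None:
        seed = Tensor(np.ones_like(output.data))
    else:
        seed = as_tensor(grad_output)
    grads: dict[int, Tensor] = {id(output): seed}
    order = _toposort(output)
    for node in reversed(order):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        for parent, vjp in zip(node._parents, node._vjps):
            if not parent.requires_grad:
                continue
            pg = vjp(g)
            acc = grads.get(id(parent))
            grads[id(parent)] = pg if acc is None else add(acc, pg)
        # keep gradients of requested leaves even if they appear mid-graph
        if any(node is w for w in wrt):
            grads[id(node)] = g
    out = []
    for w in wrt:
        gw = grads.get(id(w))
        if gw is None:
            gw = Tensor(np.zeros_like(w.data))
        out.append(gw)
    return out
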
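"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine in the micrograd lineage, extended to tensors and
to *double backward*: every vector-Jacobian product is itself expressed in
the engine's primitives, so ``grad(..., create_graph=True)`` yields gradients
that are themselves differentiable. This is what makes the second-order
teacher update of the dynamic-feedback distillation loop (an outer gradient
flowing through an inner SGD step) exact rather than approximated.

All computation is float64. The graph is built eagerly; only tensors with
``requires_grad=True`` (and their descendants, while gradients are enabled)
record parents.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "grad",
    "no_grad",
    "enable_grad",
    "concatenate",
    "where_mask",
    "relu",
    "sigmoid",
    "exp",
    "log",
    "tanh",
]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


@contextlib.contextmanager
def enable_grad(mode: bool = True):
    _GRAD_ENABLED.append(bool(mode))
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _grad_on() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    """An n-d array node in the autodiff graph."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._vjp = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _from_op(data: np.ndarray, parents: tuple, vjp) -> "Tensor":
        out = Tensor(data)
        if _grad_on() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._vjp = vjp
        return out

    # -- basic introspection ----------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        flag = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.data.shape}{flag})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def copy(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=self.requires_grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(as_tensor(other)))

    def __rsub__(self, other):
        return add(as_tensor(other), neg(self))

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes if axes else None)

    def swapaxes(self, a, b):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return transpose(self, tuple(axes))

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = 1
            for a in axes:
                n *= self.data.shape[a]
        return tsum(self, axis=axis, keepdims=keepdims) * (1.0 / n)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# broadcasting helper: reduce a cotangent back to a parent's shape
# ---------------------------------------------------------------------------


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    if g.shape == shape:
        return g
    # sum away leading broadcast axes
    while g.ndim > len(shape):
        g = tsum(g, axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = tsum(g, axis=i, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        return (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape))

    return Tensor._from_op(a.data + b.data, (a, b), vjp)


def neg(a) -> Tensor:
    a = as_tensor(a)
    return Tensor._from_op(-a.data, (a,), lambda g: (neg(g),))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        return (_unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape))

    return Tensor._from_op(a.data * b.data, (a, b), vjp)


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    c = float(exponent)

    def vjp(g):
        return (mul(g, mul(Tensor(np.float64(c)), power(a, c - 1.0))),)

    return Tensor._from_op(a.data**c, (a,), vjp)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)
    out = Tensor._from_op(out_data, (a,), None)
    if out._parents:
        out._vjp = lambda g: (mul(g, out),)
    return out


def log(a) -> Tensor:
    a = as_tensor(a)

    def vjp(g):
        return (mul(g, power(a, -1.0)),)

    return Tensor._from_op(np.log(a.data), (a,), vjp)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = Tensor((a.data > 0).astype(np.float64))

    def vjp(g):
        return (mul(g, mask),)

    return Tensor._from_op(a.data * mask.data, (a,), vjp)


def sigmoid(a) -> Tensor:
    """Numerically stable logistic; derivative expressed via the output."""
    a = as_tensor(a)
    x = a.data
    out_data = np.empty_like(x)
    pos = x >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out_data[~pos] = ex / (1.0 + ex)
    out = Tensor._from_op(out_data, (a,), None)
    if out._parents:
        out._vjp = lambda g: (mul(g, mul(out, add(1.0, neg(out)))),)
    return out


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor._from_op(np.tanh(a.data), (a,), None)
    if out._parents:
        out._vjp = lambda g: (mul(g, add(1.0, neg(mul(out, out)))),)
    return out


def where_mask(mask: np.ndarray, a, b) -> Tensor:
    """Select a where mask else b; mask is a constant boolean array."""
    a, b = as_tensor(a), as_tensor(b)
    m = Tensor(mask.astype(np.float64))
    mc = Tensor(1.0 - m.data)

    def vjp(g):
        return (_unbroadcast(mul(g, m), a.shape), _unbroadcast(mul(g, mc), b.shape))

    return Tensor._from_op(np.where(mask, a.data, b.data), (a, b), vjp)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        if b.ndim == 1:
            # a @ v : g has a's leading shape
            ga = mul(reshape(g, g.shape + (1,)), reshape(b, (1,) * (a.ndim - 1) + b.shape))
            gb = tsum(mul(reshape(g, g.shape + (1,)), a), axis=tuple(range(a.ndim - 1)))
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))
        if a.ndim == 1:
            ga = matmul(g, b.swapaxes(-1, -2))
            gb = mul(reshape(a, a.shape + (1,)), reshape(g, (1,) * (b.ndim - 2) + (1,) + g.shape[-1:]))
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))
        ga = matmul(g, b.swapaxes(-1, -2))
        gb = matmul(a.swapaxes(-1, -2), g)
        return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

    return Tensor._from_op(a.data @ b.data, (a, b), vjp)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            gg = reshape(g, (1,) * a.ndim)
        elif not keepdims:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            axes = tuple(ax % a.ndim for ax in axes)
            shp = [1 if i in axes else s for i, s in enumerate(a.shape)]
            gg = reshape(g, tuple(shp))
        else:
            gg = g
        return (broadcast_to(gg, a.shape),)

    return Tensor._from_op(out_data, (a,), vjp)


def broadcast_to(a, shape: tuple) -> Tensor:
    a = as_tensor(a)
    if a.shape == tuple(shape):
        return a

    def vjp(g):
        return (_unbroadcast(g, a.shape),)

    return Tensor._from_op(np.broadcast_to(a.data, shape), (a,), vjp)


def reshape(a, shape: tuple) -> Tensor:
    a = as_tensor(a)
    orig = a.shape

    def vjp(g):
        return (reshape(g, orig),)

    return Tensor._from_op(a.data.reshape(shape), (a,), vjp)


def transpose(a, axes=None) -> Tensor:
    a = as_tensor(a)
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    inv = tuple(np.argsort(axes))

    def vjp(g):
        return (transpose(g, inv),)

    return Tensor._from_op(a.data.transpose(axes), (a,), vjp)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)

    def vjp(g):
        return (_scatter(g, a.shape, idx),)

    return Tensor._from_op(a.data[idx], (a,), vjp)


def _scatter(g, shape: tuple, idx) -> Tensor:
    g = as_tensor(g)

    def vjp(gg):
        return (getitem(gg, idx),)

    data = np.zeros(shape, dtype=np.float64)
    np.add.at(data, idx, g.data)
    return Tensor._from_op(data, (g,), vjp)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    nd = tensors[0].ndim
    ax = axis % nd

    def vjp(g):
        outs = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = tuple(slice(None) if i != ax else slice(int(lo), int(hi)) for i in range(nd))
            outs.append(getitem(g, sl))
        return tuple(outs)

    return Tensor._from_op(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), vjp)


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------


def _topo_order(root: Tensor) -> list:
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    return order


def grad(output: Tensor, inputs, create_graph: bool = False):
    """Gradient of a scalar ``output`` with respect to ``inputs``.

    Returns one Tensor per input (zeros where the output does not depend on
    the input). With ``create_graph=True`` the returned gradients carry their
    own graph, enabling higher-order differentiation.
    """
    single = isinstance(inputs, Tensor)
    inputs = [inputs] if single else list(inputs)
    if output.data.size != 1:
        raise ValueError("grad() requires a scalar output")
    order = _topo_order(output)
    cotangents: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    keep = {id(t) for t in inputs}
    with enable_grad(create_graph):
        for node in reversed(order):
            g = cotangents.get(id(node))
            if g is None:
                continue
            if id(node) not in keep:
                cotangents.pop(id(node))
            if node._vjp is None:
                continue
            for p, pg in zip(node._parents, node._vjp(g)):
                if pg is None or not p.requires_grad:
                    continue
                acc = cotangents.get(id(p))
                cotangents[id(p)] = pg if acc is None else add(acc, pg)
    out = [cotangents.get(id(t), Tensor(np.zeros_like(t.data))) for t in inputs]
    return out[0] if single else out
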
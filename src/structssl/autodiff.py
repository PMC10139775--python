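"""Minimal reverse-mode automatic differentiation over numpy arrays.

Every primitive's vector–Jacobian product is itself expressed with traced
primitives, so :func:`grad` called with ``create_graph=True`` returns
tensors that can be differentiated again.  This is what lets the outer
level of the pseudo bi-level optimiser differentiate through the inner
gradient-ascent step.

The engine is deliberately small: float64 only, dense arrays, and just
the operations the residue-graph networks need (affine maps, ReLU,
exp/log/softplus/sigmoid, reductions, row gather/scatter, concatenation).
"""
from __future__ import annotations

from contextlib import contextmanager, nullcontext

import numpy as np

_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    """Disable graph construction inside the block."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


class Tensor:
    """A numpy array with an optional backward graph."""

    __slots__ = ("data", "parents", "vjps", "requires_grad")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents: tuple = ()
        self.vjps: tuple = ()
        self.requires_grad = bool(requires_grad)

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, c):
        return power(self, c)

    def __getitem__(self, idx):
        return take_rows(self, idx)

    @property
    def T(self):
        return transpose(self)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, vjps) -> Tensor:
    """Create a graph node; collapses to a constant when grad is off."""
    if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
        t = Tensor(data)
        t.parents = tuple(parents)
        t.vjps = tuple(vjps)
        t.requires_grad = True
        return t
    return Tensor(data)


# ---------------------------------------------------------------------
# broadcasting helper: reduce a cotangent back to a parent's shape
# ---------------------------------------------------------------------

def _sum_to(g: Tensor, shape: tuple) -> Tensor:
    while g.ndim > len(shape):
        g = tsum(g, axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = tsum(g, axis=i, keepdims=True)
    if g.shape != shape:  # e.g. scalar vs ()-shaped
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data + b.data,
        (a, b),
        (lambda g: _sum_to(g, a.shape), lambda g: _sum_to(g, b.shape)),
    )


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data - b.data,
        (a, b),
        (lambda g: _sum_to(g, a.shape), lambda g: _sum_to(neg(g), b.shape)),
    )


def neg(a) -> Tensor:
    a = as_tensor(a)
    return _node(-a.data, (a,), (lambda g: neg(g),))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data * b.data,
        (a, b),
        (lambda g: _sum_to(mul(g, b), a.shape), lambda g: _sum_to(mul(g, a), b.shape)),
    )


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data / b.data,
        (a, b),
        (
            lambda g: _sum_to(div(g, b), a.shape),
            lambda g: _sum_to(neg(div(mul(g, a), mul(b, b))), b.shape),
        ),
    )


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    return _node(
        a.data @ b.data,
        (a, b),
        (lambda g: matmul(g, transpose(b)), lambda g: matmul(transpose(a), g)),
    )


def transpose(a) -> Tensor:
    a = as_tensor(a)
    return _node(a.data.T, (a,), (lambda g: transpose(g),))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return _node(a.data.reshape(shape), (a,), (lambda g: reshape(g, a.shape),))


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)

    def vjp(g):
        if axis is None:
            return broadcast_to(reshape(g, (1,) * a.ndim), a.shape)
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        if not keepdims:
            kshape = list(a.shape)
            for ax in axes:
                kshape[ax] = 1
            g = reshape(g, tuple(kshape))
        return broadcast_to(g, a.shape)

    return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), (vjp,))


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    return _node(
        np.broadcast_to(a.data, shape).copy(), (a,), (lambda g: _sum_to(g, a.shape),)
    )


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return div(tsum(a, axis=axis, keepdims=keepdims), float(n))


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = Tensor((a.data > 0).astype(np.float64))
    return _node(a.data * mask.data, (a,), (lambda g: mul(g, mask),))


def exp(a) -> Tensor:
    a = as_tensor(a)
    return _node(np.exp(a.data), (a,), (lambda g: mul(g, exp(a)),))


def log(a) -> Tensor:
    a = as_tensor(a)
    return _node(np.log(a.data), (a,), (lambda g: div(g, a),))


def power(a, c: float) -> Tensor:
    a = as_tensor(a)
    c = float(c)
    return _node(
        a.data**c, (a,), (lambda g: mul(g, mul(Tensor(c), power(a, c - 1.0))),)
    )


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    data = np.where(
        a.data >= 0,
        1.0 / (1.0 + np.exp(-np.abs(a.data))),
        np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))),
    )
    return _node(
        data, (a,), (lambda g: mul(g, mul(sigmoid(a), sub(1.0, sigmoid(a)))),)
    )


def softplus(a) -> Tensor:
    """log(1 + e^x), evaluated stably."""
    a = as_tensor(a)
    return _node(np.logaddexp(0.0, a.data), (a,), (lambda g: mul(g, sigmoid(a)),))


def take_rows(a, idx) -> Tensor:
    """Gather along axis 0 with a slice or integer array."""
    a = as_tensor(a)
    if isinstance(idx, (list, np.ndarray)):
        idx = np.asarray(idx, dtype=np.intp)
    return _node(a.data[idx], (a,), (lambda g: scatter_rows(g, idx, a.shape),))


def scatter_rows(g, idx, shape) -> Tensor:
    """Adjoint of take_rows: scatter-add rows of g into a zero array."""
    g = as_tensor(g)

    def _fwd(data):
        out = np.zeros(shape, dtype=np.float64)
        np.add.at(out, idx, data)
        return out

    return _node(_fwd(g.data), (g,), (lambda gg: take_rows(gg, idx),))


def narrow(a, axis: int, start: int, length: int) -> Tensor:
    """Contiguous slice along one axis."""
    a = as_tensor(a)
    sl = [slice(None)] * a.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)

    def vjp(g):
        pads = []
        before = list(a.shape)
        before[axis] = start
        after = list(a.shape)
        after[axis] = a.shape[axis] - start - length
        if before[axis] > 0:
            pads.append(Tensor(np.zeros(before)))
        pads.append(g)
        if after[axis] > 0:
            pads.append(Tensor(np.zeros(after)))
        return concat(pads, axis=axis)

    return _node(a.data[sl].copy(), (a,), (vjp,))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def make_vjp(i):
        return lambda g: narrow(g, axis, int(offsets[i]), sizes[i])

    return _node(
        np.concatenate([t.data for t in tensors], axis=axis),
        tuple(tensors),
        tuple(make_vjp(i) for i in range(len(tensors))),
    )


# ---------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------

def logsumexp(a, axis: int = -1) -> Tensor:
    """Stable log-sum-exp along one axis (keepdims=False).

    The max shift is a constant, which leaves the value and every
    derivative order unchanged.
    """
    a = as_tensor(a)
    m = Tensor(np.max(a.data, axis=axis, keepdims=True))
    s = log(tsum(exp(sub(a, m)), axis=axis, keepdims=True))
    out = add(s, m)
    shape = list(a.shape)
    del shape[axis if axis >= 0 else a.ndim + axis]
    return reshape(out, tuple(shape))


def log_softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    m = Tensor(np.max(a.data, axis=axis, keepdims=True))
    shifted = sub(a, m)
    return sub(shifted, log(tsum(exp(shifted), axis=axis, keepdims=True)))


def softmax(a, axis: int = -1) -> Tensor:
    return exp(log_softmax(a, axis=axis))


# ---------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------

def grad(output: Tensor, inputs, create_graph: bool = False):
    """Gradients of a scalar ``output`` with respect to ``inputs``.

    Returns one Tensor per input (zeros where the input does not reach
    the output).  With ``create_graph=True`` the returned tensors carry
    their own backward graphs and can be differentiated again.
    """
    if output.size != 1:
        raise ValueError("grad requires a scalar output")
    # reverse topological order over the reachable differentiable subgraph
    topo: list[Tensor] = []
    visited: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in visited:
                stack.append((p, False))

    cot: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    ctx = nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(topo):
            g = cot.get(id(node))
            if g is None:
                continue
            for parent, vjp in zip(node.parents, node.vjps):
                if not parent.requires_grad:
                    continue
                contrib = vjp(g)
                prev = cot.get(id(parent))
                cot[id(parent)] = contrib if prev is None else add(prev, contrib)

    out = []
    for inp in inputs:
        g = cot.get(id(inp))
        out.append(g if g is not None else Tensor(np.zeros_like(inp.data)))
    return out
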
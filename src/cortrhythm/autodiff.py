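"""Minimal reverse-mode automatic differentiation over numpy arrays.

The hierarchical log-posteriors in :mod:`cortrhythm.model_core` need exact
gradients for Hamiltonian Monte Carlo. This module provides a small tape-based
reverse-mode engine: computations build a graph of :class:`Node` objects whose
values are numpy arrays, and :func:`grad` walks the tape backwards
accumulating vector-Jacobian products.

Only the primitives the models need are implemented; each op accepts a mix of
:class:`Node` and plain arrays/scalars (plain operands are treated as
constants and contribute no gradient).
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

__all__ = [
    "Node", "var", "value", "grad",
    "add", "sub", "mul", "div", "neg", "power", "exp", "log", "log1p",
    "sqrt", "square", "tanh", "asum", "dot", "concat", "cumsum", "cumprod",
    "reshape", "transpose", "tril",
    "sigmoid", "log_sigmoid", "log1mexp", "normal_logsf", "softplus",
    "take", "logaddexp",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class Node:
    """A value in the computation graph.

    ``parents`` is a tuple of ``(parent_node, vjp)`` pairs where ``vjp`` maps
    the incoming cotangent to the parent's cotangent.
    """

    __slots__ = ("value", "parents")

    # defer mixed numpy-array expressions to the Node operators
    __array_ufunc__ = None

    def __init__(self, value, parents=()):
        t = type(value)
        if t is np.ndarray or t is float:
            self.value = value
        elif np.ndim(value):
            self.value = np.asarray(value, dtype=float)
        else:
            self.value = float(value)
        self.parents = parents

    # -- operator sugar -----------------------------------------------------
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

    def __pow__(self, k):
        return power(self, k)

    def __matmul__(self, other):
        return dot(self, other)

    def __rmatmul__(self, other):
        return dot(other, self)

    def __getitem__(self, idx):
        return take(self, idx)

    @property
    def shape(self):
        return np.shape(self.value)


def var(x) -> Node:
    """Wrap ``x`` as a differentiable leaf."""
    return Node(x)


def value(x):
    """Underlying numpy value of a Node (identity on plain arrays)."""
    return x.value if isinstance(x, Node) else x


def _unbroadcast(g, shape):
    """Reduce cotangent ``g`` back to ``shape`` after numpy broadcasting."""
    g = np.asarray(g)
    if g.shape == shape:
        return g
    if shape == ():
        return g.sum()
    nextra = g.ndim - len(shape)
    if nextra > 0:
        g = g.sum(axis=tuple(range(nextra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _shape(v):
    return v.shape if type(v) is np.ndarray else ()


def _binary(a, b, out, vjp_a, vjp_b):
    parents = []
    if isinstance(a, Node):
        sa = _shape(a.value)
        parents.append((a, lambda g, f=vjp_a, s=sa: _unbroadcast(f(g), s)))
    if isinstance(b, Node):
        sb = _shape(b.value)
        parents.append((b, lambda g, f=vjp_b, s=sb: _unbroadcast(f(g), s)))
    return Node(out, tuple(parents))


def _unary(a, out, vjp):
    if isinstance(a, Node):
        return Node(out, ((a, vjp),))
    return Node(out)


# -- arithmetic -------------------------------------------------------------

def add(a, b):
    return _binary(a, b, value(a) + value(b), lambda g: g, lambda g: g)


def sub(a, b):
    return _binary(a, b, value(a) - value(b), lambda g: g, lambda g: -g)


def mul(a, b):
    av, bv = value(a), value(b)
    return _binary(a, b, av * bv, lambda g: g * bv, lambda g: g * av)


def div(a, b):
    av, bv = value(a), value(b)
    out = av / bv
    return _binary(a, b, out, lambda g: g / bv, lambda g: -g * out / bv)


def neg(a):
    return _unary(a, -value(a), lambda g: -g)


def power(a, k):
    """``a ** k`` for a constant exponent ``k``."""
    av = value(a)
    out = av ** k
    return _unary(a, out, lambda g: g * k * av ** (k - 1))


def exp(a):
    out = np.exp(value(a))
    return _unary(a, out, lambda g: g * out)


def log(a):
    av = value(a)
    return _unary(a, np.log(av), lambda g: g / av)


def log1p(a):
    av = value(a)
    return _unary(a, np.log1p(av), lambda g: g / (1.0 + av))


def sqrt(a):
    out = np.sqrt(value(a))
    return _unary(a, out, lambda g: g * 0.5 / out)


def square(a):
    av = value(a)
    return _unary(a, av * av, lambda g: g * 2.0 * av)


def tanh(a):
    out = np.tanh(value(a))
    return _unary(a, out, lambda g: g * (1.0 - out * out))


def logaddexp(a, b):
    av, bv = value(a), value(b)
    out = np.logaddexp(av, bv)
    return _binary(a, b, out,
                   lambda g: g * np.exp(av - out),
                   lambda g: g * np.exp(bv - out))


# -- reductions / structure --------------------------------------------------

def asum(a, axis=None):
    av = value(a)
    out = np.sum(av, axis=axis)

    def vjp(g, shape=np.shape(av), ax=axis):
        if ax is None:
            return np.broadcast_to(g, shape)
        return np.broadcast_to(np.expand_dims(g, ax), shape)

    return _unary(a, out, vjp)


def dot(a, b):
    """Matrix/vector product with the semantics of ``np.matmul``/``np.dot``."""
    av, bv = value(a), value(b)
    out = av @ bv
    a_nd, b_nd = np.ndim(av), np.ndim(bv)

    if a_nd == 2 and b_nd == 2:
        vjp_a = lambda g: g @ bv.T
        vjp_b = lambda g: av.T @ g
    elif a_nd == 2 and b_nd == 1:
        vjp_a = lambda g: np.outer(g, bv)
        vjp_b = lambda g: av.T @ g
    elif a_nd == 1 and b_nd == 2:
        vjp_a = lambda g: bv @ g
        vjp_b = lambda g: np.outer(av, g)
    elif a_nd == 1 and b_nd == 1:
        vjp_a = lambda g: g * bv
        vjp_b = lambda g: g * av
    else:  # pragma: no cover - unused rank combination
        raise ValueError("dot supports 1-D and 2-D operands only")
    return _binary(a, b, out, vjp_a, vjp_b)


def take(a, idx):
    """Indexing/slicing; integer-array ("gather") indices accumulate on backprop."""
    av = value(a)
    out = av[idx]

    def vjp(g, shape=np.shape(av), ix=idx):
        z = np.zeros(shape)
        np.add.at(z, ix, g)
        return z

    return _unary(a, out, vjp)


def concat(parts, axis=0):
    vals = [value(p) for p in parts]
    out = np.concatenate([np.atleast_1d(v) for v in vals], axis=axis)
    parents = []
    offset = 0
    for p, v in zip(parts, vals):
        n = np.atleast_1d(v).shape[axis]
        if isinstance(p, Node):
            sl = [slice(None)] * out.ndim
            sl[axis] = slice(offset, offset + n)
            scalar = np.ndim(v) == 0

            def vjp(g, s=tuple(sl), sc=scalar):
                piece = g[s]
                return piece.reshape(()) if sc else piece

            parents.append((p, vjp))
        offset += n
    return Node(out, tuple(parents))


def reshape(a, shape):
    av = value(a)
    return _unary(a, av.reshape(shape), lambda g, s=av.shape: g.reshape(s))


def transpose(a):
    av = value(a)
    return _unary(a, av.T, lambda g: g.T)


def tril(flat, d):
    """Assemble a lower-triangular (d, d) matrix from a row-major flat vector
    of its d(d+1)/2 nonzero entries."""
    idx = np.tril_indices(d)
    fv = value(flat)
    out = np.zeros((d, d))
    out[idx] = fv
    return _unary(flat, out, lambda g, ix=idx: g[ix])


def cumsum(a):
    av = value(a)
    return _unary(a, np.cumsum(av), lambda g: np.cumsum(g[::-1])[::-1])


def cumprod(a):
    """Cumulative product; gradient assumes no zero entries."""
    av = value(a)
    out = np.cumprod(av)
    return _unary(a, out, lambda g: np.cumsum((g * out)[::-1])[::-1] / av)


# -- special functions -------------------------------------------------------

def sigmoid(a):
    out = _sp.expit(value(a))
    return _unary(a, out, lambda g: g * out * (1.0 - out))


def softplus(a):
    av = value(a)
    return _unary(a, np.logaddexp(0.0, av), lambda g: g * _sp.expit(av))


def log_sigmoid(a):
    av = value(a)
    return _unary(a, -np.logaddexp(0.0, -av), lambda g: g * _sp.expit(-av))


def log1mexp(a):
    """``log(1 - exp(a))`` for ``a < 0``, computed stably."""
    av = np.asarray(value(a), dtype=float)
    out = np.where(av < -np.log(2.0), np.log1p(-np.exp(av)), np.log(-np.expm1(av)))
    if np.ndim(value(a)) == 0:
        out = float(out)
    return _unary(a, out, lambda g: -g * np.exp(av - out))


def normal_logsf(a):
    """Log survival function of the standard normal, ``log P(Z > a)``."""
    av = value(a)
    out = _sp.log_ndtr(-av)
    return _unary(a, out, lambda g: -g * np.exp(-0.5 * av * av - _LOG_SQRT_2PI - out))


# -- backward pass ------------------------------------------------------------

def grad(out: Node, wrt):
    """Gradient of scalar ``out`` with respect to leaf node(s) ``wrt``.

    Returns a single array if ``wrt`` is a Node, else a list of arrays.
    """
    single = isinstance(wrt, Node)
    targets = [wrt] if single else list(wrt)
    if np.ndim(out.value) != 0:
        raise ValueError("grad target must be scalar")

    # iterative post-order topological sort
    topo: list[Node] = []
    seen: set[int] = set()
    stack: list[tuple[Node, bool]] = [(out, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node.parents:
            if id(parent) not in seen:
                stack.append((parent, False))

    cot: dict[int, np.ndarray] = {id(out): np.ones(())}
    for node in reversed(topo):
        g = cot.get(id(node))
        if g is None:
            continue
        for parent, vjp in node.parents:
            pg = vjp(g)
            acc = cot.get(id(parent))
            cot[id(parent)] = pg if acc is None else acc + pg

    results = []
    for t in targets:
        g = cot.get(id(t))
        if g is None:
            g = np.zeros(np.shape(t.value))
        results.append(np.asarray(g))
    return results[0] if single else results
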
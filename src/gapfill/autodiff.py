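"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The recurrent imputers in this package are trained by gradient descent on an
objective built from LSTM recurrences. This module provides the small tape
needed for that: a :class:`Var` wraps an ndarray, records the operations
applied to it, and :meth:`Var.backward` accumulates exact gradients by the
chain rule. Only the primitives the sequence models use are implemented
(affine maps, elementwise gates, concatenation/slicing, masked absolute
error); every primitive's gradient is exercised against central finite
differences in the test suite.

Broadcasting follows NumPy semantics; gradients of broadcast operands are
summed back over the broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Var", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were added or stretched by broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading axes that did not exist in the original shape
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Var:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("value", "grad", "_parents", "_backward")

    # make ndarray <op> Var dispatch to the reflected Var operators
    __array_ufunc__ = None

    def __init__(self, value, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.value.shape

    # ---- graph construction -------------------------------------------------

    @staticmethod
    def _lift(other) -> "Var":
        return other if isinstance(other, Var) else Var(other)

    def __add__(self, other):
        other = Var._lift(other)
        out = Var(self.value + other.value, (self, other))

        def bw(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Var(-self.value, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-Var._lift(other))

    def __rsub__(self, other):
        return Var._lift(other) + (-self)

    def __mul__(self, other):
        other = Var._lift(other)
        out = Var(self.value * other.value, (self, other))

        def bw(g):
            return (
                _unbroadcast(g * other.value, self.shape),
                _unbroadcast(g * self.value, other.shape),
            )

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = Var._lift(other)
        out = Var(self.value @ other.value, (self, other))

        def bw(g):
            return (g @ other.value.T, self.value.T @ g)

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Var(self.value[idx], (self,))

        def bw(g):
            full = np.zeros_like(self.value)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.value))
        out = Var(s, (self,))
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def tanh(self):
        t = np.tanh(self.value)
        out = Var(t, (self,))
        out._backward = lambda g: (g * (1.0 - t * t),)
        return out

    def exp(self):
        e = np.exp(self.value)
        out = Var(e, (self,))
        out._backward = lambda g: (g * e,)
        return out

    def relu(self):
        mask = self.value > 0
        out = Var(np.where(mask, self.value, 0.0), (self,))
        out._backward = lambda g: (g * mask,)
        return out

    def abs(self):
        sign = np.sign(self.value)  # subgradient 0 at 0
        out = Var(np.abs(self.value), (self,))
        out._backward = lambda g: (g * sign,)
        return out

    def sum(self):
        out = Var(self.value.sum(), (self,))
        out._backward = lambda g: (np.broadcast_to(g, self.shape).copy(),)
        return out

    # ---- backward pass ------------------------------------------------------

    def backward(self):
        """Accumulate d(self)/d(node) into every reachable node's ``.grad``."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar objective")
        topo: list[Var] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: sequence graphs exceed recursion limits
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
        for node in topo:
            node.grad = np.zeros_like(node.value)
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                parent.grad += g


def concat(vars_: list[Var], axis: int = -1) -> Var:
    """Concatenate along an axis; gradient splits back to the operands."""
    vals = [v.value for v in vars_]
    out = Var(np.concatenate(vals, axis=axis), tuple(vars_))
    sizes = [v.shape[axis] for v in vals]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a list of leaf :class:`Var` parameters."""

    def __init__(self, params: list[Var], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
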
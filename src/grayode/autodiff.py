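"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the physics-informed network needs: dense
affine layers, elementwise nonlinearities, arithmetic with broadcasting,
reductions, and a "custom-Jacobian" node used to differentiate through an
ODE right-hand side whose analytic state Jacobian is already available.
Gradients accumulate into ``.grad`` after calling :func:`backward` on a
scalar output.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Var", "backward", "matmul", "tanh", "sin", "cos", "exp", "sigmoid",
           "concat", "sum_", "mean_", "custom_jacobian_op"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Var:
    """A node in the computation graph: value, parents, and a pull-back."""

    __slots__ = ("value", "grad", "parents", "_vjp")

    def __init__(self, value, parents: Sequence["Var"] = (),
                 vjp: Callable[[np.ndarray], tuple[np.ndarray, ...]] | None = None):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self.parents = tuple(parents)
        self._vjp = vjp

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Var":
        return other if isinstance(other, Var) else Var(other)

    def __add__(self, other):
        other = self._lift(other)
        return Var(self.value + other.value, (self, other),
                   lambda g: (_unbroadcast(g, self.value.shape),
                              _unbroadcast(g, other.value.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Var(-self.value, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        return Var(self.value * other.value, (self, other),
                   lambda g: (_unbroadcast(g * other.value, self.value.shape),
                              _unbroadcast(g * self.value, other.value.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return Var(self.value / other.value, (self, other),
                   lambda g: (_unbroadcast(g / other.value, self.value.shape),
                              _unbroadcast(-g * self.value / other.value ** 2,
                                           other.value.shape)))

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        return Var(self.value ** p, (self,),
                   lambda g: (g * p * self.value ** (p - 1),))

    def __getitem__(self, idx):
        def vjp(g):
            out = np.zeros_like(self.value)
            np.add.at(out, idx, g)
            return (out,)
        return Var(self.value[idx], (self,), vjp)

    @property
    def shape(self):
        return self.value.shape


def matmul(a: Var, b: Var) -> Var:
    a, b = Var._lift(a), Var._lift(b)
    return Var(a.value @ b.value, (a, b),
               lambda g: (g @ b.value.T, a.value.T @ g))


def tanh(x: Var) -> Var:
    x = Var._lift(x)
    t = np.tanh(x.value)
    return Var(t, (x,), lambda g: (g * (1.0 - t ** 2),))


def sin(x: Var) -> Var:
    x = Var._lift(x)
    return Var(np.sin(x.value), (x,), lambda g: (g * np.cos(x.value),))


def cos(x: Var) -> Var:
    x = Var._lift(x)
    return Var(np.cos(x.value), (x,), lambda g: (-g * np.sin(x.value),))


def exp(x: Var) -> Var:
    x = Var._lift(x)
    e = np.exp(np.clip(x.value, -500, 500))
    return Var(e, (x,), lambda g: (g * e,))


def sigmoid(x: Var) -> Var:
    x = Var._lift(x)
    s = 1.0 / (1.0 + np.exp(-np.clip(x.value, -500, 500)))
    return Var(s, (x,), lambda g: (g * s * (1.0 - s),))


def concat(vars_: Sequence[Var], axis: int = 1) -> Var:
    vars_ = [Var._lift(v) for v in vars_]
    sizes = [v.value.shape[axis] for v in vars_]
    splits = np.cumsum(sizes)[:-1]
    return Var(np.concatenate([v.value for v in vars_], axis=axis), tuple(vars_),
               lambda g: tuple(np.split(g, splits, axis=axis)))


def sum_(x: Var) -> Var:
    x = Var._lift(x)
    return Var(x.value.sum(), (x,), lambda g: (np.broadcast_to(g, x.value.shape).copy(),))


def mean_(x: Var) -> Var:
    x = Var._lift(x)
    n = x.value.size
    return Var(x.value.mean(), (x,),
               lambda g: (np.broadcast_to(g / n, x.value.shape).copy(),))


def custom_jacobian_op(inputs: Sequence[Var], value: np.ndarray,
                       vjp: Callable[[np.ndarray], tuple[np.ndarray, ...]]) -> Var:
    """Graph node with an externally supplied value and vector-Jacobian product.

    Used for ODE right-hand sides: the value is computed with plain numpy and
    the pull-back contracts the upstream gradient with the model's analytic
    state Jacobian (and finite-difference parameter sensitivities).
    """
    return Var(value, tuple(inputs), vjp)


def backward(out: Var) -> None:
    """Accumulate gradients of the scalar ``out`` into every graph node."""
    if out.value.size != 1:
        raise ValueError("backward() expects a scalar output")
    topo: list[Var] = []
    seen: set[int] = set()
    stack = [(out, False)]
    while stack:  # iterative DFS: graphs from long loss pipelines can be deep
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    out.grad = np.ones_like(out.value)
    for node in reversed(topo):
        if node._vjp is None or node.grad is None:
            continue
        for parent, g in zip(node.parents, node._vjp(node.grad)):
            if parent.grad is None:
                parent.grad = np.array(g, dtype=float, copy=True)
            else:
                parent.grad += g
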
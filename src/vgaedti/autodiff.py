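"""Minimal reverse-mode automatic differentiation on dense numpy arrays.

The package trains two graph autoencoders end-to-end with gradient descent;
this module supplies the small computation-graph machinery those models need
(matrix products, elementwise nonlinearities, reductions). It is deliberately
tiny: dense full-graph tensors only, no broadcasting beyond what the models
use, gradients accumulated by topological sweep. Every loss built on top of
it is verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


class Tensor:
    """A node in the computation graph.

    Parameters
    ----------
    value : ndarray or scalar
        The forward value.
    parents : tuple of (Tensor, callable)
        Each callable maps the gradient w.r.t. this node to the gradient
        contribution for that parent.
    requires_grad : bool
        Leaves with ``requires_grad=True`` accumulate ``.grad``.
    """

    __slots__ = ("value", "parents", "requires_grad", "grad")

    def __init__(self, value, parents=(), requires_grad=False):
        self.value = np.asarray(value, dtype=float)
        self.parents = parents
        self.requires_grad = requires_grad
        self.grad = None

    # -- graph bookkeeping -------------------------------------------------

    def _toposort(self):
        order, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for parent, _ in node.parents:
                visit(parent)
            order.append(node)

        visit(self)
        return order

    def backward(self, seed=None):
        """Backpropagate from this (scalar) node; fills ``.grad`` on leaves."""
        if seed is None:
            if self.value.ndim != 0:
                raise ValueError("backward() without seed requires a scalar")
            seed = np.ones_like(self.value)
        grads = {id(self): np.asarray(seed, dtype=float)}
        for node in reversed(self._toposort()):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            for parent, vjp in node.parents:
                contrib = vjp(g)
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + contrib
                else:
                    grads[key] = contrib

    def zero_grad(self):
        self.grad = None

    # -- conversions -------------------------------------------------------

    @property
    def shape(self):
        return self.value.shape

    def item(self):
        return float(self.value)

    def __float__(self):
        return float(self.value)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.value.shape}, grad={self.requires_grad})"

    # -- operations --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.value + other.value,
            parents=(
                (self, lambda g: _unbroadcast(g, self.value.shape)),
                (other, lambda g: _unbroadcast(g, other.value.shape)),
            ),
        )

    __radd__ = __add__

    def __sub__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.value - other.value,
            parents=(
                (self, lambda g: _unbroadcast(g, self.value.shape)),
                (other, lambda g: _unbroadcast(-g, other.value.shape)),
            ),
        )

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.value * other.value,
            parents=(
                (self, lambda g: _unbroadcast(g * other.value, self.value.shape)),
                (other, lambda g: _unbroadcast(g * self.value, other.value.shape)),
            ),
        )

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __matmul__(self, other):
        other = as_tensor(other)
        return Tensor(
            self.value @ other.value,
            parents=(
                (self, lambda g: g @ other.value.T),
                (other, lambda g: self.value.T @ g),
            ),
        )

    @property
    def T(self):
        return Tensor(self.value.T, parents=((self, lambda g: g.T),))

    def __getitem__(self, idx):
        def vjp(g):
            out = np.zeros_like(self.value)
            np.add.at(out, idx, g)
            return out

        return Tensor(self.value[idx], parents=((self, vjp),))

    def sum(self):
        return Tensor(
            self.value.sum(),
            parents=((self, lambda g: g * np.ones_like(self.value)),),
        )

    def square(self):
        return Tensor(
            self.value**2, parents=((self, lambda g: g * 2.0 * self.value),)
        )

    def exp(self):
        out = np.exp(self.value)
        return Tensor(out, parents=((self, lambda g: g * out),))

    def log(self):
        return Tensor(
            np.log(self.value), parents=((self, lambda g: g / self.value),)
        )

    def relu(self):
        mask = self.value > 0
        return Tensor(
            np.where(mask, self.value, 0.0),
            parents=((self, lambda g: g * mask),),
        )

    def leaky_relu(self, slope=0.01):
        mask = self.value > 0
        return Tensor(
            np.where(mask, self.value, slope * self.value),
            parents=((self, lambda g: g * np.where(mask, 1.0, slope)),),
        )

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.value, -500, 500)))
        return Tensor(out, parents=((self, lambda g: g * out * (1.0 - out)),))

    def clip(self, lo, hi):
        """Clamp values; gradient passes through only inside the interval."""
        mask = (self.value > lo) & (self.value < hi)
        return Tensor(
            np.clip(self.value, lo, hi), parents=((self, lambda g: g * mask),)
        )

    def detach(self):
        """A constant copy cut out of the graph (frozen during EM steps)."""
        return Tensor(self.value.copy())


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g, shape):
    """Reduce a gradient back to ``shape`` after numpy broadcasting."""
    g = np.asarray(g, dtype=float)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, n in enumerate(shape):
        if n == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g
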
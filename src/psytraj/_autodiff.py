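"""Minimal reverse-mode tensor autodiff used by the recurrent variational model.

Only the operations the encoder/decoder and mixture objective need are
implemented: elementwise arithmetic with numpy broadcasting, matmul, the
usual nonlinearities, reductions, and reshape.  Gradients are accumulated
by topological traversal of the recorded graph.  Correctness is checked by
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "sigmoid", "tanh", "exp", "log", "logsumexp", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes numpy broadcast to produce it from `shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        g = _unbroadcast(g, self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor"):
            if id(t) in seen or not (t.requires_grad or t._parents):
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- op helpers --------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
            out.requires_grad = True
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def back(g):
            self._accumulate(g)
            other._accumulate(g)

        return self._make(self.data + other.data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), back)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def back(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)

        return self._make(self.data * other.data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def back(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / other.data**2)

        return self._make(self.data / other.data, (self, other), back)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        def back(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), back)

    def __matmul__(self, other):
        other = self._lift(other)

        def back(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), back)

    # -- reductions / shape ------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def back(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape

        def back(g):
            self._accumulate(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), back)


# -- elementwise nonlinearities -------------------------------------------


def exp(t: Tensor) -> Tensor:
    out_data = np.exp(t.data)

    def back(g):
        t._accumulate(g * out_data)

    return t._make(out_data, (t,), back)


def log(t: Tensor) -> Tensor:
    def back(g):
        t._accumulate(g / t.data)

    return t._make(np.log(t.data), (t,), back)


def tanh(t: Tensor) -> Tensor:
    out_data = np.tanh(t.data)

    def back(g):
        t._accumulate(g * (1.0 - out_data**2))

    return t._make(out_data, (t,), back)


def sigmoid(t: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-t.data))

    def back(g):
        t._accumulate(g * out_data * (1.0 - out_data))

    return t._make(out_data, (t,), back)


def logsumexp(t: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp; the max shift is a constant w.r.t. grad."""
    m = np.max(t.data, axis=axis, keepdims=True)
    shifted = t - Tensor(m)
    out = log(exp(shifted).sum(axis=axis, keepdims=True)) + Tensor(m)
    if not keepdims:
        out = out.reshape(tuple(n for i, n in enumerate(t.shape) if i != axis % t.data.ndim))
    return out


def softmax(t: Tensor, axis: int) -> Tensor:
    return exp(t - logsumexp(t, axis=axis, keepdims=True))
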
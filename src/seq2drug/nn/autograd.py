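"""Minimal reverse-mode automatic differentiation on numpy arrays.

Everything is float64. Only the operations required by the interaction
network are implemented: broadcasting arithmetic, (batched) matmul,
reductions, elementwise nonlinearities, reshape/transpose/indexing, and a
numerically stable softmax / softplus. Gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` via topological sort.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "relu", "sigmoid", "tanh", "softmax", "softplus"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading added axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _needs(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, self._needs(other), (self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = back
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, self._needs(other), (self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, self._needs(other), (self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = back
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, self._needs(other), (self, other))

        def back(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = back
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = back
        return out

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = back
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def back(g):
            if self.requires_grad:
                self._accumulate(g.transpose(*inv))

        out._backward = back
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = back
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(g * val)

        out._backward = back
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = back
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A tensor registered as trainable by :class:`seq2drug.nn.layers.Module`."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, x.requires_grad, (x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = back
    return out


def sigmoid(x: Tensor) -> Tensor:
    val = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(val, x.requires_grad, (x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g * val * (1.0 - val))

    out._backward = back
    return out


def tanh(x: Tensor) -> Tensor:
    val = np.tanh(x.data)
    out = Tensor(val, x.requires_grad, (x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - val**2))

    out._backward = back
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # max-shift is a constant w.r.t. differentiation
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)) computed stably; d/dx = sigmoid(x)."""
    val = np.maximum(x.data, 0.0) + np.log1p(np.exp(-np.abs(x.data)))
    out = Tensor(val, x.requires_grad, (x,))
    sig = 1.0 / (1.0 + np.exp(-x.data))

    def back(g):
        if x.requires_grad:
            x._accumulate(g * sig)

    out._backward = back
    return out
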
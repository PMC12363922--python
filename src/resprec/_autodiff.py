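"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to train the small multilayer perceptrons and
conditional flows used by the counterfactual engine: a tape-recorded
``Tensor`` wrapper, broadcasting-aware elementwise ops, matmul, reductions,
and an Adam optimiser.  Nothing here is model-specific.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "concat", "where"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("value", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, value, parents=(), backward=None, requires_grad=False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.value.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g

    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        # iterative post-order DFS for a topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.value + other.value, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.value.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.value.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.value * other.value, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.value, self.value.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.value, other.value.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.value / other.value, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.value, self.value.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.value / other.value**2, other.value.shape)
                )

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.value @ other.value, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.value.T)
            if other.requires_grad:
                other._accum(self.value.T @ g)

        out._backward = bw
        return out

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out = Tensor(np.exp(self.value), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out.value)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.value), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.value)

        out._backward = bw
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.value), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out.value**2))

        out._backward = bw
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.value)), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out.value * (1.0 - out.value))

        out._backward = bw
        return out

    def sinh(self):
        out = Tensor(np.sinh(self.value), (self,))
        ch = np.cosh(self.value)

        def bw(g):
            if self.requires_grad:
                self._accum(g * ch)

        out._backward = bw
        return out

    def asinh(self):
        out = Tensor(np.arcsinh(self.value), (self,))
        d = 1.0 / np.sqrt(1.0 + self.value**2)

        def bw(g):
            if self.requires_grad:
                self._accum(g * d)

        out._backward = bw
        return out

    def log_cosh(self):
        # numerically stable log(cosh(x)) = |x| + log1p(exp(-2|x|)) - log 2
        ax = np.abs(self.value)
        out = Tensor(ax + np.log1p(np.exp(-2 * ax)) - np.log(2.0), (self,))
        th = np.tanh(self.value)

        def bw(g):
            if self.requires_grad:
                self._accum(g * th)

        out._backward = bw
        return out

    def leaky_relu(self, slope: float = 0.1):
        mask = self.value > 0
        out = Tensor(np.where(mask, self.value, slope * self.value), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * np.where(mask, 1.0, slope))

        out._backward = bw
        return out

    def square(self):
        return self * self

    def abs(self):
        sign = np.sign(self.value)
        out = Tensor(np.abs(self.value), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * sign)

        out._backward = bw
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if self.requires_grad:
                g = np.asarray(g)
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.value.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def __getitem__(self, idx):
        out = Tensor(self.value[idx], (self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.value)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bw
        return out


class Parameter(Tensor):
    def __init__(self, value):
        super().__init__(value, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    vals = [t.value for t in tensors]
    out = Tensor(np.concatenate(vals, axis=axis), tuple(tensors))
    splits = np.cumsum([v.shape[axis] for v in vals])[:-1]

    def bw(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bw
    return out


def where(cond: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor._lift(a), Tensor._lift(b)
    out = Tensor(np.where(cond, a.value, b.value), (a, b))

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(np.where(cond, g, 0.0), a.value.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(np.where(cond, 0.0, g), b.value.shape))

    out._backward = bw
    return out


class Adam:
    """Adam optimiser over a flat list of Parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-2,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.value
            )
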
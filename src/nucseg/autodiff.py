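"""Reverse-mode automatic differentiation over NumPy arrays.

A compact tape-based engine sized for the desk-scale networks in this
package.  Every :class:`Tensor` wraps a ``float64`` ndarray; operations
build a DAG and :meth:`Tensor.backward` runs reverse accumulation in
topological order.  Broadcasting follows NumPy semantics; gradients are
summed back over broadcast axes.

Only the operations the segmentation networks need are provided.  All
computation is deterministic: no threading, no in-place aliasing of
tape nodes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "as_tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A differentiable multidimensional array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward_fn=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = parents
        self._backward_fn = backward_fn

    # -- bookkeeping ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-accumulate gradients from this node to all leaves."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward_fn is not None and t.grad is not None:
                t._backward_fn(t.grad)

    # -- arithmetic ----------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other.accumulate(_unbroadcast(g, other.data.shape))
        out._backward_fn = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.accumulate(-g)
        out._backward_fn = bw
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other.accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward_fn = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.accumulate(g * p * self.data ** (p - 1))
        out._backward_fn = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self.accumulate(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other.accumulate(self.data.swapaxes(-1, -2) @ g)
        out._backward_fn = bw
        return out

    # -- elementwise ---------------------------------------------------

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.accumulate(g * val)
        out._backward_fn = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.accumulate(g / self.data)
        out._backward_fn = bw
        return out

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.accumulate(g * mask)
        out._backward_fn = bw
        return out

    def sigmoid(self):
        val = np.where(self.data >= 0,
                       1.0 / (1.0 + np.exp(-np.abs(self.data))),
                       np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))))
        out = Tensor(val, self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.accumulate(g * val * (1 - val))
        out._backward_fn = bw
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.accumulate(g * sign)
        out._backward_fn = bw
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where unclamped."""
        mask = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.accumulate(g * mask)
        out._backward_fn = bw
        return out

    # -- reductions & shaping -----------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.accumulate(np.broadcast_to(gg, self.data.shape).copy())
        out._backward_fn = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self.accumulate(g.reshape(self.data.shape))
        out._backward_fn = bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes), self.requires_grad, parents=(self,))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self.accumulate(g.transpose(inv))
        out._backward_fn = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                gg = np.zeros_like(self.data)
                np.add.at(gg, idx, g)
                self.accumulate(gg)
        out._backward_fn = bw
        return out


class Parameter(Tensor):
    """A trainable tensor."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t.accumulate(p)
    out._backward_fn = bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), parents=tuple(tensors))

    def bw(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t.accumulate(p.squeeze(axis=axis) if p.shape != t.data.shape else p)
    out._backward_fn = bw
    return out
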
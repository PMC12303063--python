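"""Minimal reverse-mode automatic differentiation on numpy arrays.

The networks in this package are a handful of affine layers, so a small
tape-based autodiff is sufficient: a :class:`Tensor` wraps an ndarray,
records the operation that produced it, and ``backward()`` accumulates
gradients by reverse topological traversal.  Broadcasting follows numpy
semantics; gradients of broadcast operands are summed back to the operand
shape.  Everything is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "logsumexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100.0  # numpy defers binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy(), requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other), None)
        if out.requires_grad:
            out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other), None)
        if out.requires_grad:
            out._backward = lambda g: (
                self._accum(g * other.data),
                other._accum(g * self.data),
            )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = self._make(self.data / other.data, (self, other), None)
        if out.requires_grad:
            out._backward = lambda g: (
                self._accum(g / other.data),
                other._accum(-g * self.data / other.data**2),
            )
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)
        out = self._make(self.data**p, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = self._make(self.data @ other.data, (self, other), None)
        if out.requires_grad:

            def back(g):
                a, b = self.data, other.data
                if a.ndim == 1 and b.ndim == 2:
                    self._accum(g @ b.T)
                    other._accum(np.outer(a, g))
                elif a.ndim == 2 and b.ndim == 1:
                    self._accum(np.outer(g, b))
                    other._accum(a.T @ g)
                else:
                    self._accum(g @ np.swapaxes(b, -1, -2))
                    other._accum(np.swapaxes(a, -1, -2) @ g)

            out._backward = back
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,), None)
        if out.requires_grad:

            def back(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

            out._backward = back
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        if out.requires_grad:

            def back(g):
                g = np.asarray(g)
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))

            out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def cumsum_reverse(self, axis: int = 0):
        """Suffix sums along `axis` (used for Cox risk-set accumulation)."""
        rev = np.flip(np.cumsum(np.flip(self.data, axis), axis=axis), axis)
        out = self._make(rev, (self,), None)
        if out.requires_grad:
            # d suffix-sum / dx is a prefix sum of the incoming gradient
            out._backward = lambda g: self._accum(np.cumsum(g, axis=axis))
        return out

    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    # ----------------------------------------------------------- element-wise
    def exp(self):
        e = np.exp(self.data)
        out = self._make(e, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        s = np.sqrt(self.data)
        out = self._make(s, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * 0.5 / s)
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = self._make(t, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * (1.0 - t**2))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = self._make(s, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def softplus(self):
        # numerically stable log(1 + e^x)
        sp = np.logaddexp(0.0, self.data)
        out = self._make(sp, (self,), None)
        if out.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
            out._backward = lambda g: self._accum(g * sig)
        return out

    def clip(self, lo: float, hi: float):
        out = self._make(np.clip(self.data, lo, hi), (self,), None)
        if out.requires_grad:
            mask = (self.data > lo) & (self.data < hi)
            out._backward = lambda g: self._accum(g * mask)
        return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor._make(data, tuple(tensors), None)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def back(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                t._accum(piece)

        out._backward = back
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor._make(data, tuple(tensors), None)
    if out.requires_grad:

        def back(g):
            for i, t in enumerate(tensors):
                t._accum(np.take(g, i, axis=axis))

        out._backward = back
    return out


def logsumexp(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    """Stable log-sum-exp; the max shift is treated as a constant."""
    m = np.max(x.data, axis=axis, keepdims=True)
    shifted = x - Tensor(m)
    s = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    if not keepdims and axis is not None:
        s = s.reshape(np.squeeze(s.data, axis=axis).shape)
    elif not keepdims and axis is None:
        s = s.reshape(())
    return s
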
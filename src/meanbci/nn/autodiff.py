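"""Reverse-mode autodiff over NumPy arrays.

A :class:`Tensor` wraps an ndarray and records the closure that propagates
its output gradient to its parents; ``backward()`` runs the closures in
reverse topological order.  Broadcasting is handled by summing gradients
over broadcast axes.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- plumbing -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

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

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        a, b = self, Tensor._lift(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    # -- shape --------------------------------------------------------------

    def reshape(self, *shape):
        a = self
        old = a.shape

        def bwd(g):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return Tensor._make(a.data.reshape(*shape), (a,), bwd)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def bwd(g):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bwd)

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        a = self
        idx = np.argmax(a.data, axis=axis)
        out = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)

        def bwd(g):
            if not a.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            grad = np.zeros_like(a.data)
            np.put_along_axis(grad, np.expand_dims(idx, axis), gg, axis=axis)
            a._accum(grad)

        return Tensor._make(out if keepdims else np.squeeze(out, axis), (a,), bwd)

    # -- nonlinearities ------------------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), bwd)

    def relu6(self):
        a = self
        mask = (a.data > 0) & (a.data < 6.0)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._make(np.clip(a.data, 0.0, 6.0), (a,), bwd)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return Tensor._make(s, (a,), bwd)

    def tanh(self):
        a = self
        t = np.tanh(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * (1.0 - t * t))

        return Tensor._make(t, (a,), bwd)

    # -- losses --------------------------------------------------------------

    def softmax_cross_entropy(self, labels: np.ndarray) -> "Tensor":
        """Mean cross-entropy of logits (B, C) against integer labels (B,)."""
        a = self
        z = a.data - a.data.max(axis=1, keepdims=True)
        ez = np.exp(z)
        p = ez / ez.sum(axis=1, keepdims=True)
        b = a.data.shape[0]
        loss = -np.mean(np.log(p[np.arange(b), labels] + 1e-300))

        def bwd(g):
            if a.requires_grad:
                grad = p.copy()
                grad[np.arange(b), labels] -= 1.0
                a._accum(g * grad / b)

        return Tensor._make(loss, (a,), bwd)

    def softmax_probs(self) -> np.ndarray:
        """Plain softmax of the underlying data (no gradient tracking)."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=-1, keepdims=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, o0, o1 in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(o0, o1)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), bwd)


def stack_params(tensors: list[Tensor]) -> list[Tensor]:
    """Flat view helper used by optimizers/serialization."""
    return list(tensors)
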
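"""Minimal reverse-mode automatic differentiation on NumPy arrays.

All model components in this package (protein projection, MPNN encoder,
cross-coupled fusion, MLP head) are differentiable compositions of the small
op set below.  Everything runs in float64: the package targets desk-scale
problems where numerical transparency matters more than throughput.

Design notes
------------
* A :class:`Tensor` wraps an ``ndarray`` plus an optional backward closure.
  ``backward()`` runs a single reverse topological sweep and accumulates
  gradients into every reachable ``requires_grad`` leaf.
* Broadcasting in ``+``/``*`` is supported; gradients are un-broadcast by
  summing over the expanded axes.
* ``matmul`` supports stacked (batched) operands via ``np.matmul`` semantics.
* ``segment_sum`` / integer-array indexing provide the scatter/gather pair
  used for message passing on graphs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "segment_sum", "relu", "exp", "log", "sigmoid"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        data = self.data + other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._node(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        data = self.data * other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._node(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        data = self.data / other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data**2), b.data.shape))

        return Tensor._node(data, (self, other), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        # promote 1-D operands through reshape nodes so the core backward
        # only ever sees stacked 2-D matmuls
        if self.ndim == 1:
            return (self.reshape(1, -1) @ other).reshape(-1) if other.ndim > 1 else \
                (self.reshape(1, -1) @ other.reshape(-1, 1)).reshape(())
        if other.ndim == 1:
            return (self @ other.reshape(-1, 1)).reshape(self.shape[:-1])
        data = np.matmul(self.data, other.data)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(np.matmul(g, np.swapaxes(b.data, -1, -2)), a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(np.matmul(np.swapaxes(a.data, -1, -2), g), b.data.shape))

        return Tensor._node(data, (self, other), backward)

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._node(data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        data = self.data.reshape(shape)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(np.asarray(g).reshape(a.data.shape))

        return Tensor._node(data, (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def transpose(self, axes=None):
        data = self.data.T if axes is None else self.data.transpose(axes)

        def backward(g, a=self, axes=axes):
            if not a.requires_grad:
                return
            if axes is None:
                a._accum(np.asarray(g).T)
            else:
                a._accum(np.asarray(g).transpose(np.argsort(axes)))

        return Tensor._node(data, (self,), backward)

    def __getitem__(self, key):
        data = self.data[key]
        # basic slicing selects disjoint positions, so += suffices; integer
        # arrays may repeat indices and need the unbuffered scatter-add
        basic = isinstance(key, (slice, int)) or (
            isinstance(key, tuple) and all(isinstance(k, (slice, int)) for k in key)
        )

        def backward(g, a=self, key=key, basic=basic):
            if not a.requires_grad:
                return
            if a.grad is None:
                a.grad = np.zeros_like(a.data)
            if basic:
                a.grad[key] += g
            else:
                np.add.at(a.grad, key, g)

        return Tensor._node(data, (self,), backward)

    # -- autograd plumbing ----------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


# -- elementwise nonlinearities -----------------------------------------------

def relu(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    mask = x.data > 0

    def backward(g, a=x, mask=mask):
        if a.requires_grad:
            a._accum(g * mask)

    return Tensor._node(x.data * mask, (x,), backward)


def exp(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    data = np.exp(x.data)

    def backward(g, a=x, data=data):
        if a.requires_grad:
            a._accum(g * data)

    return Tensor._node(data, (x,), backward)


def log(x: Tensor) -> Tensor:
    x = Tensor._lift(x)

    def backward(g, a=x):
        if a.requires_grad:
            a._accum(g / a.data)

    return Tensor._node(np.log(x.data), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g, a=x, data=data):
        if a.requires_grad:
            a._accum(g * data * (1.0 - data))

    return Tensor._node(data, (x,), backward)


# -- structural ops -----------------------------------------------------------

def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors, offsets=offsets, axis=axis):
        g = np.asarray(g)
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._node(data, tuple(tensors), backward)


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `x` into `num_segments` buckets given per-row ids."""
    x = Tensor._lift(x)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    data = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(data, segment_ids, x.data)

    def backward(g, a=x, ids=segment_ids):
        if a.requires_grad:
            a._accum(np.asarray(g)[ids])

    return Tensor._node(data, (x,), backward)
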
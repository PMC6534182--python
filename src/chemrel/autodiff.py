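"""Minimal reverse-mode automatic differentiation over NumPy arrays.

All neural blocks in this package (LSTM gates, scaled dot-product
attention, attention pooling, the bidirectional language model) are
expressed as compositions of the primitives below, so a single backward
pass provides exact gradients.  Everything runs in float64; finite
difference checks in the test-suite hold each primitive to a relative
error below 1e-4.

The design follows the classic tape-based pattern: each :class:`Tensor`
records its parents and a closure that routes the output gradient back
to them; ``backward`` topologically sorts the graph and accumulates.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A float64 array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = ()

    # -- helpers -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out._prev = tuple(p for p in parents if isinstance(p, Tensor))
        out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self._backward is None and not self.requires_grad:
            return  # constant leaf: gradient not wanted
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        return self._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            a, b = self.data, other.data
            if b.ndim == 1:
                if a.ndim == 1:
                    ga, gb = g * b, g * a
                else:
                    ga = g[..., None] * b
                    gb = (a * g[..., None]).reshape(-1, b.shape[0]).sum(axis=0)
            elif a.ndim == 1:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
                gb = np.multiply.outer(a, g)
            else:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
                gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accum(_unbroadcast(np.asarray(ga), a.shape))
            other._accum(_unbroadcast(np.asarray(gb), b.shape))

        return self._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities ------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    # -- reductions & shaping ------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, a, b):
        def backward(g):
            self._accum(np.swapaxes(g, a, b))

        return self._make(np.swapaxes(self.data, a, b), (self,), backward)

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    # -- softmax family (numerically stable primitives) ----------------
    def softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return self._make(out_data, (self,), backward)

    def log_softmax(self, axis=-1):
        m = self.data.max(axis=axis, keepdims=True)
        lse = m + np.log(np.exp(self.data - m).sum(axis=axis, keepdims=True))
        out_data = self.data - lse

        def backward(g):
            soft = np.exp(out_data)
            self._accum(g - soft * g.sum(axis=axis, keepdims=True))

        return self._make(out_data, (self,), backward)

    # -- gather / scatter primitives -----------------------------------
    def take_rows(self, idx):
        """Embedding lookup: rows of a 2-D table indexed by an int array."""
        idx = np.asarray(idx)
        out_data = self.data[idx]

        def backward(g):
            if self._backward is None and not self.requires_grad:
                return
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            np.add.at(self.grad, idx, g)

        return self._make(out_data, (self,), backward)

    def take_time(self, idx):
        """Per-row gather along the time axis of a (B, T, D) tensor.

        ``idx`` is (B, T); output[b, t] = self[b, idx[b, t]].  Used to
        reverse variable-length sequences inside a padded batch.
        """
        idx = np.asarray(idx)
        rows = np.arange(self.data.shape[0])[:, None]
        out_data = self.data[rows, idx]

        def backward(g):
            if self._backward is None and not self.requires_grad:
                return
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            np.add.at(self.grad, (rows, idx), g)

        return self._make(out_data, (self,), backward)

    def select_time(self, t):
        """Slice one timestep from a (B, T, D) tensor -> (B, D)."""

        def backward(g):
            if self._backward is None and not self.requires_grad:
                return
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            self.grad[:, t, :] += g

        return self._make(self.data[:, t, :], (self,), backward)

    # -- autodiff driver -----------------------------------------------
    def backward(self, grad=None):
        topo, seen = [], set()

        def visit(node):
            stack = [(node, iter(node._prev))]
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                advanced = False
                for child in it:
                    if id(child) not in seen:
                        seen.add(id(child))
                        stack.append((child, iter(child._prev)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack.pop()

        visit(self)
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors, axis=-1):
    """Differentiable concatenation along ``axis``."""
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return tensors[0]._make(out_data, tensors, backward)


def stack(tensors, axis=1):
    """Differentiable stack along a new axis (default: time axis 1)."""
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    return tensors[0]._make(out_data, tensors, backward)
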
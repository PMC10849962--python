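"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The engine supports exactly the operations the borylation networks need:
dense affine maps, SiLU/sigmoid nonlinearities, row gather/scatter for
message passing on edge lists, segment sums for neighbourhood aggregation
and graph pooling, concatenation, and elementwise arithmetic.  Gradients
are accumulated by topologically ordered backward traversal.

Arrays are float64 throughout; reproducibility is favoured over speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "segment_sum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = back
        return out

    # ------------------------------------------------------------ nonlinear
    def square(self):
        out = Tensor(self.data**2, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(2.0 * self.data * g)
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            p * self.data ** (p - 1.0) * g
        )
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(e * g)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(s * (1.0 - s) * g)
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(self.data * s, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            (s + self.data * s * (1.0 - s)) * g
        )
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                ge = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(ge, self.data.shape).copy())

        out._backward = back
        return out

    def mean(self):
        return self.sum() * (1.0 / self.data.size)

    # --------------------------------------------------------- restructuring
    def take_rows(self, idx: np.ndarray):
        """Gather rows (message-passing source/target selection)."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], parents=(self,))

        def back(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx, g)
                self._accum(acc)

        out._backward = back
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.data.shape)
        )
        return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along `axis` with gradient routing back to each input."""
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = back
    return out


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Row-wise scatter-add: out[k] = sum of rows i with segment_ids[i] == k.

    Used both for neighbourhood aggregation (segments = target atoms) and for
    graph pooling (segments = molecule ids in a batch).  Segments with no
    members yield zero rows, matching the empty-neighbourhood convention.
    """
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    data = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(data, segment_ids, x.data)
    out = Tensor(data, parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g[segment_ids])
    return out
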
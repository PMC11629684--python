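"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Everything trainable in this package (geometric vector perceptrons,
attention blocks, the molecular message-passing encoder, the prediction
head) is expressed with the :class:`Tensor` operations defined here.
Arrays are kept in float64 throughout so invariance and algebra tests can
use tight tolerances.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concatenate", "stack", "segment_sum", "segment_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # remove leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents = tuple(_parents)
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS: graphs here can be thousands of nodes deep
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data / other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / other.data)
            if other.requires_grad:
                other._accumulate(-g * self.data / other.data**2)

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data @ other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bwd(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    self._accumulate(np.outer(g, other.data) if self.data.ndim == 2 else g * other.data)
                elif self.data.ndim == 1:
                    self._accumulate(g @ other.data.swapaxes(-1, -2))
                else:
                    self._accumulate(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                if self.data.ndim == 1:
                    other._accumulate(np.outer(self.data, g) if other.data.ndim == 2 else self.data * g)
                else:
                    other._accumulate(self.data.swapaxes(-1, -2) @ g)

        out._backward = bwd
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # ----------------------------------------------------------- elementwise
    def _unary(self, value: np.ndarray, dfn: Callable[[], np.ndarray]) -> "Tensor":
        out = Tensor(value, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * dfn())

        out._backward = bwd
        return out

    def exp(self):
        value = np.exp(self.data)
        return self._unary(value, lambda: value)

    def log(self):
        return self._unary(np.log(self.data), lambda: 1.0 / self.data)

    def sqrt(self):
        value = np.sqrt(self.data)
        return self._unary(value, lambda: 0.5 / value)

    def tanh(self):
        value = np.tanh(self.data)
        return self._unary(value, lambda: 1.0 - value**2)

    def sigmoid(self):
        value = 1.0 / (1.0 + np.exp(-self.data))
        return self._unary(value, lambda: value * (1.0 - value))

    def relu(self):
        mask = self.data > 0
        return self._unary(self.data * mask, lambda: mask.astype(np.float64))

    def leaky_relu(self, slope: float = 0.1):
        mask = self.data > 0
        scale = np.where(mask, 1.0, slope)
        return self._unary(self.data * scale, lambda: scale)

    # ------------------------------------------------------------ structural
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g.reshape(orig))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(self.data.swapaxes(a, b), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g.swapaxes(a, b))
        return out

    @property
    def T(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = bwd
        return out

    # ------------------------------------------------------------- compound
    def softmax(self, axis: int = -1):
        """Softmax along `axis`; max-shift is detached (gradient-exact)."""
        shift = self - np.max(self.data, axis=axis, keepdims=True)
        e = shift.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def norm(self, axis: int = -1, keepdims: bool = False, eps: float = 1e-12):
        """Safe Euclidean norm along `axis` (smooth at zero via eps)."""
        return ((self**2).sum(axis=axis, keepdims=keepdims) + eps).sqrt()

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)


# ---------------------------------------------------------------- free ops
def concatenate(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
        tensors,
    )
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(
        np.stack([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
        tensors,
    )

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    out._backward = bwd
    return out


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `x` into `num_segments` buckets given per-row ids."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    value = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(value, segment_ids, x.data)
    out = Tensor(value, x.requires_grad, (x,))
    out._backward = lambda g: x.requires_grad and x._accumulate(g[segment_ids])
    return out


def segment_softmax(logits: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of a flat logit vector within each segment.

    Used for neighbor attention on graphs with varying degree.  The
    per-segment max-shift is detached, which leaves the gradient exact.
    """
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, segment_ids, logits.data)
    shifted = logits - seg_max[segment_ids]
    e = shifted.exp()
    denom = segment_sum(e, segment_ids, num_segments)
    return e / denom[segment_ids]
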
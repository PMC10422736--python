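"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the reaction encoder and regression head
need: dense linear algebra, elementwise nonlinearities, concatenation,
row gather/scatter (for message passing over directed edge lists) and
reductions. Everything is float64 and fully deterministic.

Gradient correctness is checked against central finite differences in the
test suite; do not add an op without such a check.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather_rows",
    "matmul",
    "relu",
    "segment_max",
    "segment_sum",
    "sigmoid",
    "stack_rows",
    "tanh",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # Sum over leading axes added by broadcasting.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # Sum over axes that were 1 in the original shape.
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus the backward closure that built it."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = tuple(parents)
        self._backward = backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape})"

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward(g: np.ndarray) -> None:
            _accum(self, _unbroadcast(g, self.data.shape))
            _accum(other, _unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __sub__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data - other.data, (self, other))

        def backward(g: np.ndarray) -> None:
            _accum(self, _unbroadcast(g, self.data.shape))
            _accum(other, _unbroadcast(-g, other.data.shape))

        out._backward = backward
        return out

    def __mul__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward(g: np.ndarray) -> None:
            _accum(self, _unbroadcast(g * other.data, self.data.shape))
            _accum(other, _unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], (self,))

        def backward(g: np.ndarray) -> None:
            full = np.zeros_like(self.data)
            full[key] = g
            _accum(self, full)

        out._backward = backward
        return out

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), (self,))

        def backward(g: np.ndarray) -> None:
            _accum(self, g.reshape(self.data.shape))

        out._backward = backward
        return out

    def sum(self, axis: int | None = None) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis), (self,))

        def backward(g: np.ndarray) -> None:
            if axis is None:
                _accum(self, np.full_like(self.data, float(g)))
            else:
                _accum(self, np.broadcast_to(np.expand_dims(g, axis), self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis: int | None = None) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    # -- autograd driver -------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from a scalar output through the whole graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    t.grad = g if t.grad is None else t.grad + g


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))

    def backward(g: np.ndarray) -> None:
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0), (x,))

    def backward(g: np.ndarray) -> None:
        _accum(x, g * mask)

    out._backward = backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, (x,))

    def backward(g: np.ndarray) -> None:
        _accum(x, g * s * (1.0 - s))

    out._backward = backward
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, (x,))

    def backward(g: np.ndarray) -> None:
        _accum(x, g * (1.0 - t * t))

    out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray) -> None:
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    out._backward = backward
    return out


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Rows x[index]; gradient scatter-adds back into x."""
    index = np.asarray(index, dtype=np.intp)
    out = Tensor(x.data[index], (x,))

    def backward(g: np.ndarray) -> None:
        full = np.zeros_like(x.data)
        np.add.at(full, index, g)
        _accum(x, full)

    out._backward = backward
    return out


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of x into `num_segments` buckets; empty buckets are zero."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    data = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(data, segment_ids, x.data)
    out = Tensor(data, (x,))

    def backward(g: np.ndarray) -> None:
        _accum(x, g[segment_ids])

    out._backward = backward
    return out


def segment_max(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Elementwise max of rows of x per bucket; empty buckets are zero.

    Gradient flows to the first row attaining the max in each bucket.
    """
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    data = np.full((num_segments,) + x.data.shape[1:], -np.inf)
    np.maximum.at(data, segment_ids, x.data)
    empty = np.isinf(data)
    data[empty] = 0.0
    # winner[s, j] = index of the first row in bucket s attaining the max.
    winner = np.full(data.shape, -1, dtype=np.intp)
    for i in range(len(segment_ids) - 1, -1, -1):
        s = segment_ids[i]
        winner[s][x.data[i] == data[s]] = i
    out = Tensor(data, (x,))

    def backward(g: np.ndarray) -> None:
        full = np.zeros_like(x.data)
        rows, cols = np.nonzero(winner >= 0)
        np.add.at(full, (winner[rows, cols], cols), g[rows, cols])
        _accum(x, full)

    out._backward = backward
    return out


def stack_rows(tensors: list[Tensor]) -> Tensor:
    """Stack 1-D tensors (or same-shape tensors) along a new first axis."""
    out = Tensor(np.stack([t.data for t in tensors]), tuple(tensors))

    def backward(g: np.ndarray) -> None:
        for i, t in enumerate(tensors):
            _accum(t, g[i])

    out._backward = backward
    return out
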
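"""A compact reverse-mode automatic differentiation tape over numpy arrays.

Just enough machinery for recurrent sequence models: broadcast-aware
arithmetic, matmul, sigmoid/tanh, concatenation, indexing and a numerically
stable log-sum-exp.  Every op builds a node holding its parents and the
local vector-Jacobian products; ``backward`` walks the graph once in
reverse topological order.  float64 throughout.
"""
from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

ArrayLike = Union[float, int, np.ndarray, "Tensor"]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("value", "grad", "parents", "requires_grad")

    def __init__(
        self,
        value: ArrayLike,
        parents: Sequence[Tuple["Tensor", Callable[[np.ndarray], np.ndarray]]] = (),
        requires_grad: bool = False,
    ) -> None:
        if isinstance(value, Tensor):
            raise TypeError("nested Tensor")
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.parents = tuple(parents)
        self.requires_grad = requires_grad or any(
            p.requires_grad for p, _ in parents
        )

    # -- graph traversal ---------------------------------------------------
    def backward(self, seed: Optional[np.ndarray] = None) -> None:
        if seed is None:
            if self.value.size != 1:
                raise ValueError("backward() without seed needs a scalar")
            seed = np.ones_like(self.value)
        topo: List[Tensor] = []
        visited = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent, _ in node.parents:
                stack.append((parent, False))
        self.grad = np.asarray(seed, dtype=np.float64)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, vjp in node.parents:
                if not parent.requires_grad:
                    continue
                contrib = vjp(node.grad)
                if parent.grad is None:
                    parent.grad = contrib.copy()
                else:
                    parent.grad += contrib

    def zero_grad(self) -> None:
        self.grad = None

    # -- shape helpers -----------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.value.shape

    def reshape(self, *shape) -> "Tensor":
        orig = self.value.shape
        return Tensor(
            self.value.reshape(*shape),
            [(self, lambda g: g.reshape(orig))],
        )

    def __getitem__(self, key) -> "Tensor":
        def vjp(g: np.ndarray) -> np.ndarray:
            out = np.zeros_like(self.value)
            np.add.at(out, key, g)
            return out
        return Tensor(self.value[key], [(self, vjp)])

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: ArrayLike) -> "Tensor":
        other = as_tensor(other)
        return Tensor(
            self.value + other.value,
            [
                (self, lambda g: _unbroadcast(g, self.value.shape)),
                (other, lambda g: _unbroadcast(g, other.value.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor(-self.value, [(self, lambda g: -g)])

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other: ArrayLike) -> "Tensor":
        other = as_tensor(other)
        return Tensor(
            self.value * other.value,
            [
                (self, lambda g: _unbroadcast(g * other.value, self.value.shape)),
                (other, lambda g: _unbroadcast(g * self.value, other.value.shape)),
            ],
        )

    __rmul__ = __mul__

    def __matmul__(self, other: ArrayLike) -> "Tensor":
        other = as_tensor(other)
        a, b = self.value, other.value
        return Tensor(
            a @ b,
            [
                (self, lambda g: _unbroadcast(g @ b.swapaxes(-1, -2), a.shape)),
                (other, lambda g: _unbroadcast(a.swapaxes(-1, -2) @ g, b.shape)),
            ],
        )

    def sum(self, axis=None) -> "Tensor":
        shape = self.value.shape

        def vjp(g: np.ndarray) -> np.ndarray:
            if axis is None:
                return np.broadcast_to(g, shape).copy()
            return np.broadcast_to(np.expand_dims(g, axis), shape).copy()

        return Tensor(self.value.sum(axis=axis), [(self, vjp)])


def as_tensor(x: ArrayLike) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(value: np.ndarray) -> Tensor:
    return Tensor(value, requires_grad=True)


def sigmoid(x: Tensor) -> Tensor:
    out = np.where(
        x.value >= 0,
        1.0 / (1.0 + np.exp(-np.abs(x.value))),
        np.exp(-np.abs(x.value)) / (1.0 + np.exp(-np.abs(x.value))),
    )
    return Tensor(out, [(x, lambda g: g * out * (1.0 - out))])


def tanh(x: Tensor) -> Tensor:
    out = np.tanh(x.value)
    return Tensor(out, [(x, lambda g: g * (1.0 - out * out))])


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    values = [t.value for t in tensors]
    sizes = [v.shape[axis] for v in values]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i: int):
        sl = [slice(None)] * values[i].ndim
        def vjp(g: np.ndarray) -> np.ndarray:
            sl[axis] = slice(offsets[i], offsets[i + 1])
            return g[tuple(sl)]
        return vjp

    return Tensor(
        np.concatenate(values, axis=axis),
        [(t, make_vjp(i)) for i, t in enumerate(tensors)],
    )


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def make_vjp(i: int):
        return lambda g: np.take(g, i, axis=axis)

    return Tensor(
        np.stack([t.value for t in tensors], axis=axis),
        [(t, make_vjp(i)) for i, t in enumerate(tensors)],
    )


def logsumexp(x: Tensor, axis: Optional[int] = None) -> Tensor:
    m = np.max(x.value, axis=axis, keepdims=True)
    shifted = np.exp(x.value - m)
    total = shifted.sum(axis=axis, keepdims=True)
    out = m + np.log(total)
    softmax = shifted / total
    if axis is not None:
        out_val = np.squeeze(out, axis=axis)
    else:
        out_val = out.reshape(())

    def vjp(g: np.ndarray) -> np.ndarray:
        if axis is None:
            return softmax * g
        return softmax * np.expand_dims(g, axis)

    return Tensor(out_val, [(x, vjp)])


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout: identity at prediction time."""
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.value.shape) >= rate) / (1.0 - rate)
    return x * mask
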
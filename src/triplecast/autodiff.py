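"""Minimal reverse-mode automatic differentiation over numpy arrays.

The whole cascade (encoder, linear-chain CRF likelihood, binary taggers) is
small enough that a compact tape-based engine is sufficient: a ``Tensor``
wraps an ``ndarray``, records its parents and a backward closure, and
``backward()`` runs the topologically-sorted tape.  Only the operations the
model actually uses are implemented — elementwise arithmetic with numpy
broadcasting, matmul, the usual nonlinearities, axis reductions including a
numerically stable ``logsumexp``, masked ``where``, and an embedding-style
row gather with scatter-add backward.

Gradient correctness is enforced by central finite differences in the test
suite; everything downstream (CRF NLL, tagger losses) inherits it.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "sigmoid", "tanh", "exp", "log", "logsumexp", "where",
           "embedding", "concat", "softmax_lastaxis"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # numpy defers to our __radd__ etc.

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction -----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[["Tensor"], None] | None) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad and backward is not None:
            out._parents = tuple(parents)
            out._backward = lambda: backward(out)
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)

        def back(out):
            self._accum(out.grad)
            other._accum(out.grad)

        return Tensor._make(self.data + other.data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(out):
            self._accum(-out.grad)

        return Tensor._make(-self.data, (self,), back)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def back(out):
            self._accum(out.grad * other.data)
            other._accum(out.grad * self.data)

        return Tensor._make(self.data * other.data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)

        def back(out):
            self._accum(out.grad / other.data)
            other._accum(-out.grad * self.data / (other.data ** 2))

        return Tensor._make(self.data / other.data, (self, other), back)

    def __matmul__(self, other):
        other = Tensor._lift(other)

        def back(out):
            g = out.grad
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                self._accum(g * b)
                other._accum(g * a)
            elif b.ndim == 1:
                self._accum(np.expand_dims(g, -1) * b)
                other._accum(_unbroadcast(
                    (np.expand_dims(g, -1) * a).reshape(-1, a.shape[-1]).sum(0),
                    b.shape))
            elif a.ndim == 1:
                self._accum(g @ np.swapaxes(b, -1, -2))
                other._accum(np.outer(a, g))
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
                self._accum(_unbroadcast(ga, a.shape))
                other._accum(_unbroadcast(gb, b.shape))

        return Tensor._make(self.data @ other.data, (self, other), back)

    # -- shape ------------------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape

        def back(out):
            self._accum(out.grad.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), back)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def back(out):
            self._accum(out.grad.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), back)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, key):
        def back(out):
            g = np.zeros_like(self.data)
            np.add.at(g, key, out.grad)
            self._accum(g)

        return Tensor._make(self.data[key], (self,), back)

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def back(out):
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: tapes can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()


# -- elementwise nonlinearities -------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    s = 1.0 / (1.0 + np.exp(-x.data))

    def back(out):
        x._accum(out.grad * s * (1.0 - s))

    return Tensor._make(s, (x,), back)


def tanh(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    t = np.tanh(x.data)

    def back(out):
        x._accum(out.grad * (1.0 - t * t))

    return Tensor._make(t, (x,), back)


def exp(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    e = np.exp(x.data)

    def back(out):
        x._accum(out.grad * e)

    return Tensor._make(e, (x,), back)


def log(x: Tensor) -> Tensor:
    x = Tensor._lift(x)

    def back(out):
        x._accum(out.grad / x.data)

    return Tensor._make(np.log(x.data), (x,), back)


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp reduction along ``axis``."""
    x = Tensor._lift(x)
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    s = e.sum(axis=axis, keepdims=True)
    val = np.log(s) + m
    soft = e / s  # softmax along axis

    def back(out):
        g = out.grad
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._accum(g * soft)

    return Tensor._make(val if keepdims else np.squeeze(val, axis=axis),
                        (x,), back)


def softmax_lastaxis(x: Tensor) -> Tensor:
    """Softmax along the last axis (used by the attention contextualizer)."""
    return exp(x - logsumexp(x, axis=-1, keepdims=True))


def where(cond: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Elementwise select with gradients routed to the taken branch.

    ``cond`` is a plain boolean array, never differentiated.
    """
    a, b = Tensor._lift(a), Tensor._lift(b)
    cond = np.asarray(cond, dtype=bool)

    def back(out):
        a._accum(np.where(cond, out.grad, 0.0))
        b._accum(np.where(cond, 0.0, out.grad))

    return Tensor._make(np.where(cond, a.data, b.data), (a, b), back)


def embedding(table: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather ``table[idx]`` with scatter-add backward.

    ``idx`` is an integer array of any shape; the result has shape
    ``idx.shape + (table.shape[1],)``.
    """
    idx = np.asarray(idx, dtype=np.intp)

    def back(out):
        g = np.zeros_like(table.data)
        np.add.at(g, idx.reshape(-1),
                  out.grad.reshape(-1, table.data.shape[1]))
        table._accum(g)

    return Tensor._make(table.data[idx], (table,), back)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(out):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(lo, hi)
            t._accum(out.grad[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, back)
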
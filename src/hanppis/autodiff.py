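"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network in :mod:`hanppis.han_model` is small (two Bi-GRU levels over
length-:math:`\\le 15` windows), so a lightweight tape suffices: every
operation records its parents and a vector-Jacobian product, and
``Tensor.backward`` walks the tape in reverse topological order.  All data
is float64; gradients are accumulated into ``Tensor.grad``.

Only the primitives the model needs are implemented (broadcast arithmetic,
matmul with a 2-D right operand, slicing, stack/concat, the usual
pointwise nonlinearities, reductions, and a masked softmax whose weights
are *exactly* zero on masked positions).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "stack",
    "sigmoid",
    "tanh",
    "relu",
    "exp",
    "log",
    "clip",
    "softmax",
    "masked_softmax",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    # make `ndarray <op> Tensor` dispatch to the Tensor reflected operator
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._vjp: Callable | None = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _op(data, parents: Sequence["Tensor"], vjp: Callable) -> "Tensor":
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out = Tensor(data, requires_grad=True)
            out._parents = tuple(parents)
            out._vjp = vjp
            return out
        return Tensor(data)

    # -- properties -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        a, b = self, Tensor._lift(other)
        return Tensor._op(
            a.data + b.data,
            (a, b),
            lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._op(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)
        return Tensor._op(
            a.data * b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._lift(other)
        return Tensor._op(
            a.data / b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g / b.data, a.data.shape),
                _unbroadcast(-g * a.data / b.data**2, b.data.shape),
            ),
        )

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)
        if b.data.ndim != 2:
            raise ValueError("matmul: right operand must be 2-D")
        out = a.data @ b.data

        def vjp(g):
            ga = g @ b.data.T
            gb = a.data.reshape(-1, a.data.shape[-1]).T @ g.reshape(-1, g.shape[-1])
            return ga, gb

        return Tensor._op(out, (a, b), vjp)

    def __getitem__(self, key):
        a = self

        def vjp(g):
            out = np.zeros_like(a.data)
            out[key] = g
            return (out,)

        return Tensor._op(a.data[key], (a,), vjp)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        a = self
        return Tensor._op(
            a.data.reshape(*shape), (a,), lambda g: (g.reshape(a.data.shape),)
        )

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, a.data.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, a.data.shape).copy(),)

        return Tensor._op(a.data.sum(axis=axis, keepdims=keepdims), (a,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        # reverse topological order over the tape
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack_.pop()
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._vjp is None:  # leaf
                if node.requires_grad:
                    node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


# -- free functions ----------------------------------------------------------


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._op(np.concatenate([t.data for t in tensors], axis=axis), tensors, vjp)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]

    def vjp(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor._op(np.stack([t.data for t in tensors], axis=axis), tensors, vjp)


def sigmoid(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    with np.errstate(over="ignore"):
        y = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor._op(y, (x,), lambda g: (g * y * (1.0 - y),))


def tanh(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    y = np.tanh(x.data)
    return Tensor._op(y, (x,), lambda g: (g * (1.0 - y**2),))


def relu(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    return Tensor._op(np.maximum(x.data, 0.0), (x,), lambda g: (g * (x.data > 0),))


def exp(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    y = np.exp(x.data)
    return Tensor._op(y, (x,), lambda g: (g * y,))


def log(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    return Tensor._op(np.log(x.data), (x,), lambda g: (g / x.data,))


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip values; gradient is zero outside the open interval."""
    x = Tensor._lift(x)
    inside = (x.data > lo) & (x.data < hi)
    return Tensor._op(np.clip(x.data, lo, hi), (x,), lambda g: (g * inside,))


def masked_softmax(x: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax over the unmasked entries; masked entries get weight exactly 0.

    ``mask`` is a constant 0/1 array broadcastable to ``x``.  Rows with no
    unmasked entry yield all-zero weights (their gradient is zero too).
    """
    x = Tensor._lift(x)
    m = np.broadcast_to(np.asarray(mask, dtype=np.float64), x.data.shape)
    neg = np.where(m > 0, x.data, -np.inf)
    mx = np.max(neg, axis=axis, keepdims=True)
    mx = np.where(np.isfinite(mx), mx, 0.0)  # all-masked rows
    e = np.exp(x.data - mx) * m
    tot = e.sum(axis=axis, keepdims=True)
    y = e / np.maximum(tot, np.finfo(np.float64).tiny)

    def vjp(g):
        return (y * (g - (g * y).sum(axis=axis, keepdims=True)),)

    return Tensor._op(y, (x,), vjp)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return masked_softmax(x, np.ones_like(Tensor._lift(x).data), axis=axis)
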
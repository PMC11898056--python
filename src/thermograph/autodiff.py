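"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model in this package is small (dense matrices at protein scale, a few
hundred residues), so a compact tape-based engine is sufficient: a
:class:`Tensor` wraps an ``ndarray``, records the operation that produced it,
and :meth:`Tensor.backward` walks the tape in reverse topological order
accumulating gradients.  Gradients of every primitive are verified against
central finite differences in the test suite.

Only the primitives the thermostability model needs are provided: affine
algebra (``+ - * / @``, transpose, powers), the nonlinearities (ReLU, tanh,
sigmoid, softplus), reductions (sum/mean), row selection, concatenation and a
numerically stable softmax / log-softmax.  Broadcasting follows numpy rules;
gradients are summed over broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "relu",
    "tanh",
    "sigmoid",
    "softplus",
    "exp",
    "log",
    "sqrt",
    "softmax",
    "log_softmax",
    "concatenate",
    "stack",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff machinery ---------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every tape ancestor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order of the tape
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
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
                order.append(node)
                stack.pop()
        for node in order:
            node.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    def _needs_tape(self, *others: "Tensor") -> bool:
        return self.requires_grad or any(o.requires_grad for o in others)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, self._needs_tape(other))
        if out.requires_grad:
            out._parents = (self, other)

            def _bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.shape))

            out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, self._needs_tape(other))
        if out.requires_grad:
            out._parents = (self, other)

            def _bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.shape))

            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * (as_tensor(other) ** -1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * (self ** -1.0)

    def __pow__(self, exponent: float):
        exponent = float(exponent)
        out = Tensor(self.data ** exponent, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw(g):
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

            out._backward = _bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, self._needs_tape(other))
        if out.requires_grad:
            out._parents = (self, other)

            a, b = self.data, other.data

            def _bw(g):
                # handle the 1-D vector cases of numpy matmul explicitly
                if self.requires_grad:
                    if a.ndim == 1 and b.ndim == 1:
                        self._accumulate(g * b)
                    elif a.ndim == 1:  # (k,) @ (k, m) -> (m,)
                        self._accumulate(g @ b.T)
                    elif b.ndim == 1:  # (n, k) @ (k,) -> (n,)
                        self._accumulate(np.outer(g, b))
                    else:
                        self._accumulate(g @ b.T)
                if other.requires_grad:
                    if a.ndim == 1 and b.ndim == 1:
                        other._accumulate(g * a)
                    elif a.ndim == 1:  # grad of (k, m) weight
                        other._accumulate(np.outer(a, g))
                    elif b.ndim == 1:
                        other._accumulate(a.T @ g)
                    else:
                        other._accumulate(a.T @ g)

            out._backward = _bw
        return out

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g.T)
        return out

    # -- reductions / selection ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())

            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def rows(self, index) -> "Tensor":
        """Select rows (first-axis fancy indexing)."""
        index = np.asarray(index)
        out = Tensor(self.data[index], self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, index, g)
                self._accumulate(full)

            out._backward = _bw
        return out


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


# -- elementwise nonlinearities ----------------------------------------------

def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.maximum(x.data, 0.0), x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)
        out._backward = lambda g: x._accumulate(g * (x.data > 0.0))
    return out


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    t = np.tanh(x.data)
    out = Tensor(t, x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)
        out._backward = lambda g: x._accumulate(g * (1.0 - t * t))
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = 0.5 * (1.0 + np.tanh(0.5 * x.data))  # stable logistic
    out = Tensor(s, x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)
        out._backward = lambda g: x._accumulate(g * s * (1.0 - s))
    return out


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), computed without overflow."""
    x = as_tensor(x)
    v = np.logaddexp(0.0, x.data)
    out = Tensor(v, x.requires_grad)
    if out.requires_grad:
        s = 0.5 * (1.0 + np.tanh(0.5 * x.data))
        out._parents = (x,)
        out._backward = lambda g: x._accumulate(g * s)
    return out


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    e = np.exp(x.data)
    out = Tensor(e, x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)
        out._backward = lambda g: x._accumulate(g * e)
    return out


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.log(x.data), x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)
        out._backward = lambda g: x._accumulate(g / x.data)
    return out


def sqrt(x: Tensor) -> Tensor:
    return x ** 0.5


# -- softmax family -----------------------------------------------------------

def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    m = x.data.max(axis=axis, keepdims=True)
    shifted = x.data - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True)) + m
    out = Tensor(x.data - lse, x.requires_grad)
    if out.requires_grad:
        p = np.exp(out.data)
        out._parents = (x,)

        def _bw(g):
            x._accumulate(g - p * g.sum(axis=axis, keepdims=True))

        out._backward = _bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    p = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(p, x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)

        def _bw(g):
            inner = (g * p).sum(axis=axis, keepdims=True)
            x._accumulate(p * (g - inner))

        out._backward = _bw
    return out


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
    )
    if out.requires_grad:
        out._parents = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def _bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)

        out._backward = _bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.stack([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
    )
    if out.requires_grad:
        out._parents = tuple(tensors)

        def _bw(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accumulate(np.take(g, i, axis=axis))

        out._backward = _bw
    return out
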
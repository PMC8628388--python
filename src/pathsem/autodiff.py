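"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for the path-scoring models: elementwise arithmetic
with broadcasting, matrix/vector products, the nonlinearities used by the
models (tanh, ReLU, sigmoid, softplus, exp, log), reductions, stacking,
row/element indexing and concatenation.  Gradients are accumulated by a
topological backward sweep from a scalar loss.

This is an internal engine; model code should read as the math it computes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "tanh",
    "relu",
    "sigmoid",
    "softplus",
    "exp",
    "log",
    "tsum",
    "dot",
    "stack",
    "index",
    "take_row",
    "gather",
    "transpose",
    "concat",
    "softmax",
    "logsumexp",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    grad = np.asarray(grad, dtype=float)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float ndarray."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, parents=(), backward=None, requires_grad=True):
        self.value = np.asarray(value, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph mechanics -------------------------------------------------

    @property
    def shape(self):
        return self.value.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.value.ndim != 0:
            raise ValueError("backward() requires a scalar (0-d) tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack_.append((p, False))
        for node in topo:
            if node.grad is None:
                node.grad = np.zeros_like(node.value)
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += _unbroadcast(grad, self.value.shape)

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = _wrap(other)
        out = Tensor(self.value + other.value, (self, other))
        out._backward = lambda g: (self._accumulate(g), other._accumulate(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out = Tensor(self.value * other.value, (self, other))
        out._backward = lambda g: (
            self._accumulate(g * other.value),
            other._accumulate(g * self.value),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        out = Tensor(self.value / other.value, (self, other))
        out._backward = lambda g: (
            self._accumulate(g / other.value),
            other._accumulate(-g * self.value / other.value**2),
        )
        return out

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __matmul__(self, other):
        other = _wrap(other)
        a, b = self, other
        out = Tensor(a.value @ b.value, (a, b))

        def backward(g):
            av, bv = a.value, b.value
            if av.ndim == 1 and bv.ndim == 1:  # dot product
                a._accumulate(g * bv)
                b._accumulate(g * av)
            elif av.ndim == 1 and bv.ndim == 2:  # (n,)@(n,m)->(m,)
                a._accumulate(bv @ g)
                b._accumulate(np.outer(av, g))
            elif av.ndim == 2 and bv.ndim == 1:  # (m,n)@(n,)->(m,)
                a._accumulate(np.outer(g, bv))
                b._accumulate(av.T @ g)
            else:  # 2-D @ 2-D
                a._accumulate(g @ bv.T)
                b._accumulate(av.T @ g)

        out._backward = backward
        return out

    def __rmatmul__(self, other):
        return _wrap(other) @ self

    def item(self) -> float:
        return float(self.value)


def _wrap(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(x, requires_grad=False)


def constant(x) -> Tensor:
    """A graph leaf that never accumulates gradient."""
    return Tensor(x, requires_grad=False)


# -- elementwise functions ----------------------------------------------


def _unary(x: Tensor, value: np.ndarray, local_grad: np.ndarray) -> Tensor:
    out = Tensor(value, (x,))
    out._backward = lambda g: x._accumulate(g * local_grad)
    return out


def tanh(x: Tensor) -> Tensor:
    v = np.tanh(x.value)
    return _unary(x, v, 1.0 - v**2)


def relu(x: Tensor) -> Tensor:
    v = np.maximum(x.value, 0.0)
    return _unary(x, v, (x.value > 0).astype(float))


def sigmoid(x: Tensor) -> Tensor:
    v = 0.5 * (1.0 + np.tanh(0.5 * x.value))  # numerically stable logistic
    return _unary(x, v, v * (1.0 - v))


def softplus(x: Tensor) -> Tensor:
    v = np.logaddexp(0.0, x.value)
    s = 0.5 * (1.0 + np.tanh(0.5 * x.value))
    return _unary(x, v, s)


def exp(x: Tensor) -> Tensor:
    v = np.exp(x.value)
    return _unary(x, v, v)


def log(x: Tensor) -> Tensor:
    return _unary(x, np.log(x.value), 1.0 / x.value)


def tsum(x: Tensor) -> Tensor:
    out = Tensor(x.value.sum(), (x,))
    out._backward = lambda g: x._accumulate(np.full_like(x.value, float(g)))
    return out


def dot(a: Tensor, b: Tensor) -> Tensor:
    return a @ b


# -- structural ops ------------------------------------------------------


def stack(tensors: list[Tensor]) -> Tensor:
    """Stack 0-d tensors into a vector, or 1-d tensors into a matrix."""
    if not tensors:
        raise ValueError("cannot stack an empty list")
    out = Tensor(np.stack([t.value for t in tensors]), tuple(tensors))

    def backward(g):
        for i, t in enumerate(tensors):
            t._accumulate(g[i])

    out._backward = backward
    return out


def index(x: Tensor, i: int) -> Tensor:
    out = Tensor(x.value[i], (x,))

    def backward(g):
        full = np.zeros_like(x.value)
        full[i] = g
        x._accumulate(full)

    out._backward = backward
    return out


take_row = index  # row of a matrix / element of a vector


def gather(x: Tensor, indices) -> Tensor:
    """Rows ``x[indices]`` of a matrix (or elements of a vector); the
    backward pass scatter-adds, so repeated indices accumulate."""
    idx = np.asarray(indices, dtype=np.int64)
    out = Tensor(x.value[idx], (x,))

    def backward(g):
        full = np.zeros_like(x.value)
        np.add.at(full, idx, g)
        x._accumulate(full)

    out._backward = backward
    return out


def transpose(x: Tensor) -> Tensor:
    out = Tensor(x.value.T, (x,))
    out._backward = lambda g: x._accumulate(np.asarray(g).T)
    return out


def concat(a: Tensor, b: Tensor) -> Tensor:
    na = a.value.shape[0]
    out = Tensor(np.concatenate([a.value, b.value]), (a, b))
    out._backward = lambda g: (a._accumulate(g[:na]), b._accumulate(g[na:]))
    return out


def softmax(z: Tensor) -> Tensor:
    """Softmax of a 1-d tensor, max-stabilized."""
    shift = z - float(z.value.max())
    e = exp(shift)
    return e / tsum(e)


def logsumexp(z: Tensor) -> Tensor:
    """log(sum(exp(z))) of a 1-d tensor, max-stabilized."""
    m = float(z.value.max())
    return log(tsum(exp(z - m))) + m
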
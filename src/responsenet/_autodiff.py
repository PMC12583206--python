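"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model's losses are compositions of dense linear maps, gated recurrences
and elementwise nonlinearities on small arrays, so a tape-based scalar-output
engine is sufficient.  Every operation records its inputs and a closure that
accumulates the vector-Jacobian product; :meth:`Tensor.backward` walks the
tape in reverse topological order.

Gradient correctness is established against central finite differences in
the test suite rather than assumed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "stack",
    "exp",
    "log",
    "tanh",
    "sigmoid",
    "softplus",
    "relu",
    "sqrt",
    "softmax",
    "sum_",
    "mean_",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    # make numpy defer `ndarray <op> Tensor` to the reflected Tensor ops
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, seed: np.ndarray | None = None) -> None:
        """Accumulate gradients of this (typically scalar) node into leaves."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS; recursion depth can exceed limits on long tapes
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            pending = [p for p in node._prev if id(p) not in seen]
            if pending:
                stack.append(node)
                stack.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
        if seed is None:
            seed = np.ones_like(self.data)
        self._accum(seed)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _node(self.data + other.data, (self, other))
        if out._prev:
            def _bw(g, a=self, b=other):
                if a.requires_grad or a._prev:
                    a._accum(g)
                if b.requires_grad or b._prev:
                    b._accum(g)
            out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        if out._prev:
            out._backward = lambda g, a=self: a._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _node(self.data * other.data, (self, other))
        if out._prev:
            def _bw(g, a=self, b=other):
                if a.requires_grad or a._prev:
                    a._accum(g * b.data)
                if b.requires_grad or b._prev:
                    b._accum(g * a.data)
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _node(self.data / other.data, (self, other))
        if out._prev:
            def _bw(g, a=self, b=other):
                if a.requires_grad or a._prev:
                    a._accum(g / b.data)
                if b.requires_grad or b._prev:
                    b._accum(-g * a.data / b.data**2)
            out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)
        out = _node(self.data**p, (self,))
        if out._prev:
            out._backward = lambda g, a=self: a._accum(g * p * a.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _node(self.data @ other.data, (self, other))
        if out._prev:
            def _bw(g, a=self, b=other):
                ad, bd = a.data, b.data
                g = np.asarray(g, dtype=np.float64)
                # promote 1-d operands to matrices (numpy's @ semantics)
                a2 = ad.reshape(1, -1) if ad.ndim == 1 else ad
                b2 = bd.reshape(-1, 1) if bd.ndim == 1 else bd
                g2 = g
                if ad.ndim == 1 and bd.ndim == 1:
                    g2 = g.reshape(1, 1)
                elif ad.ndim == 1:
                    g2 = np.expand_dims(g, -2)
                elif bd.ndim == 1:
                    g2 = np.expand_dims(g, -1)
                if a.requires_grad or a._prev:
                    ga = g2 @ np.swapaxes(b2, -1, -2)
                    a._accum(_unbroadcast(ga, a2.shape).reshape(ad.shape))
                if b.requires_grad or b._prev:
                    gb = np.swapaxes(a2, -1, -2) @ g2
                    b._accum(_unbroadcast(gb, b2.shape).reshape(bd.shape))
            out._backward = _bw
        return out

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    # -- shape ops -----------------------------------------------------
    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))
        if out._prev:
            parts = idx if isinstance(idx, tuple) else (idx,)
            advanced = any(isinstance(p, (list, np.ndarray)) for p in parts)

            def _bw(g, a=self, idx=idx, advanced=advanced):
                buf = np.zeros_like(a.data)
                if advanced:
                    np.add.at(buf, idx, g)  # handles repeated indices
                else:
                    buf[idx] += g
                a._accum(buf)
            out._backward = _bw
        return out

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))
        if out._prev:
            out._backward = lambda g, a=self: a._accum(g.reshape(a.data.shape))
        return out

    @property
    def T(self):
        out = _node(self.data.T, (self,))
        if out._prev:
            out._backward = lambda g, a=self: a._accum(g.T)
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._prev:
            def _bw(g, a=self, axis=axis, keepdims=keepdims):
                if axis is None:
                    a._accum(np.broadcast_to(g, a.data.shape))
                else:
                    if not keepdims:
                        g = np.expand_dims(g, axis)
                    a._accum(np.broadcast_to(g, a.data.shape))
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    """Create an interior node; drop parents that carry no gradient."""
    track = tuple(p for p in parents if p.requires_grad or p._prev)
    return Tensor(data, _prev=track if track else ())


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise functions
def _unary(x: Tensor, value: np.ndarray, local_grad: np.ndarray) -> Tensor:
    out = _node(value, (x,))
    if out._prev:
        out._backward = lambda g, a=x, lg=local_grad: a._accum(g * lg)
    return out


def exp(x) -> Tensor:
    x = as_tensor(x)
    v = np.exp(x.data)
    return _unary(x, v, v)


def log(x) -> Tensor:
    x = as_tensor(x)
    return _unary(x, np.log(x.data), 1.0 / x.data)


def tanh(x) -> Tensor:
    x = as_tensor(x)
    v = np.tanh(x.data)
    return _unary(x, v, 1.0 - v**2)


def sigmoid(x) -> Tensor:
    x = as_tensor(x)
    v = 0.5 * (1.0 + np.tanh(0.5 * x.data))  # numerically stable
    return _unary(x, v, v * (1.0 - v))


def softplus(x) -> Tensor:
    x = as_tensor(x)
    d = x.data
    v = np.logaddexp(0.0, d)
    return _unary(x, v, 0.5 * (1.0 + np.tanh(0.5 * d)))


def relu(x) -> Tensor:
    x = as_tensor(x)
    return _unary(x, np.maximum(x.data, 0.0), (x.data > 0).astype(np.float64))


def sqrt(x) -> Tensor:
    x = as_tensor(x)
    v = np.sqrt(x.data)
    return _unary(x, v, 0.5 / v)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Softmax along `axis`; max-shift is a constant, safe under autodiff."""
    x = as_tensor(x)
    shifted = x - np.max(x.data, axis=axis, keepdims=True)
    e = exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._prev:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def _bw(g, ts=tensors, splits=splits, axis=axis):
            for t, piece in zip(ts, np.split(g, splits, axis=axis)):
                if t.requires_grad or t._prev:
                    t._accum(piece)

        out._backward = _bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._prev:
        def _bw(g, ts=tensors, axis=axis):
            for i, t in enumerate(ts):
                if t.requires_grad or t._prev:
                    t._accum(np.take(g, i, axis=axis))
        out._backward = _bw
    return out


def sum_(x: Tensor, axis=None, keepdims=False) -> Tensor:
    return as_tensor(x).sum(axis=axis, keepdims=keepdims)


def mean_(x: Tensor, axis=None, keepdims=False) -> Tensor:
    return as_tensor(x).mean(axis=axis, keepdims=keepdims)
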
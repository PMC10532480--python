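"""Minimal reverse-mode automatic differentiation on numpy arrays.

The graph models in this package are small (a few MLPs and a GRU cell over
25-node skeleton graphs), so a compact tape-based engine is sufficient.
Every :class:`Tensor` wraps a float64 ndarray; operations record their
parents and a backward closure, and :meth:`Tensor.backward` runs reverse
topological accumulation.

The functional helpers at the bottom (``relu``, ``sigmoid``, ``concat``,
``segment_sum`` ...) dispatch on input type so that the same model forward
code runs either on plain ndarrays (fast inference path) or on Tensors
(training path with gradients).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "relu",
    "sigmoid",
    "tanh",
    "exp",
    "sqrt",
    "tsum",
    "concat",
    "gather",
    "segment_sum",
    "reshape",
    "swapaxes",
    "softmax_lastaxis",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were size 1 in the original
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    # defer mixed ndarray/Tensor arithmetic to the reflected operators
    __array_ufunc__ = None

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape})"

    # ------------------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of this tensor w.r.t. every leaf."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # iterative topological sort (post-order)
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad):
        self.grad = grad if self.grad is None else self.grad + grad

    # -- elementwise arithmetic ----------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, (self, other))

        def bwd(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p):
        if not isinstance(p, (int, float)):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data**p, (self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bwd(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        out._backward = bwd
        return out

    def __rmatmul__(self, other):
        return _as_tensor(other) @ self

    # -- reductions & shaping ------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def swapaxes(self, a, b):
        out = Tensor(np.swapaxes(self.data, a, b), (self,))
        out._backward = lambda g: self._accum(np.swapaxes(g, a, b))
        return out

    # -- nonlinearities -------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def sigmoid(self):
        # numerically stable logistic
        x = self.data
        val = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                       np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = Tensor(val, (self,))
        out._backward = lambda g: self._accum(g * val * (1.0 - val))
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, (self,))
        out._backward = lambda g: self._accum(g * (1.0 - val**2))
        return out

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, (self,))
        out._backward = lambda g: self._accum(g * val)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, (self,))
        out._backward = lambda g: self._accum(g * 0.5 / val)
        return out


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


# ----------------------------------------------------------------------
# dual-mode functional helpers: ndarray in -> ndarray out, Tensor in ->
# Tensor out.  Model forward code is written once against these.
# ----------------------------------------------------------------------

def relu(x):
    return x.relu() if isinstance(x, Tensor) else np.maximum(x, 0.0)


def sigmoid(x):
    if isinstance(x, Tensor):
        return x.sigmoid()
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                    np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))


def tanh(x):
    return x.tanh() if isinstance(x, Tensor) else np.tanh(x)


def exp(x):
    return x.exp() if isinstance(x, Tensor) else np.exp(x)


def sqrt(x):
    return x.sqrt() if isinstance(x, Tensor) else np.sqrt(x)


def tsum(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.sum(axis=axis, keepdims=keepdims)
    return x.sum(axis=axis, keepdims=keepdims)


def concat(xs, axis=-1):
    if any(isinstance(x, Tensor) for x in xs):
        xs = [_as_tensor(x) for x in xs]
        data = np.concatenate([x.data for x in xs], axis=axis)
        out = Tensor(data, tuple(xs))
        sizes = [x.data.shape[axis] for x in xs]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            for x, piece in zip(xs, np.split(g, splits, axis=axis)):
                x._accum(piece)

        out._backward = bwd
        return out
    return np.concatenate(xs, axis=axis)


def gather(x, idx):
    """Row selection ``x[idx]`` along axis 0."""
    idx = np.asarray(idx)
    if isinstance(x, Tensor):
        out = Tensor(x.data[idx], (x,))

        def bwd(g):
            gx = np.zeros_like(x.data)
            np.add.at(gx, idx, g)
            x._accum(gx)

        out._backward = bwd
        return out
    return x[idx]


def segment_sum(x, idx, n):
    """Sum rows of ``x`` into ``n`` buckets given by ``idx`` (axis 0)."""
    idx = np.asarray(idx)
    if isinstance(x, Tensor):
        data = np.zeros((n,) + x.data.shape[1:], dtype=np.float64)
        np.add.at(data, idx, x.data)
        out = Tensor(data, (x,))
        out._backward = lambda g: x._accum(g[idx])
        return out
    out = np.zeros((n,) + x.shape[1:], dtype=np.float64)
    np.add.at(out, idx, x)
    return out


def reshape(x, shape):
    if isinstance(x, Tensor):
        return x.reshape(shape)
    return x.reshape(shape)


def swapaxes(x, a, b):
    if isinstance(x, Tensor):
        return x.swapaxes(a, b)
    return np.swapaxes(x, a, b)


def softmax_lastaxis(scores):
    """Softmax over the last axis, stable via a detached max shift."""
    raw = scores.data if isinstance(scores, Tensor) else scores
    shift = np.max(raw, axis=-1, keepdims=True)
    e = exp(scores - shift)
    return e / tsum(e, axis=-1, keepdims=True)
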
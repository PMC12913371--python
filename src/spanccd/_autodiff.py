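"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical core used by the trainable span encoder and the
training objectives.  It implements exactly the operations the model
needs (dense matmul, elementwise nonlinearities, row softmax with
optional masking, layer normalisation, gathers and segment max-pooling)
with vectorised forward and backward passes.  It is intentionally small:
no graphs across devices, no in-place mutation, 64-bit floats
throughout so that runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "take_rows",
    "span_max",
    "softmax",
    "masked_softmax",
    "layer_norm",
    "relu",
    "sigmoid",
    "log",
    "exp",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, name=""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.name = name

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self)=1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bwd
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.T)

        out._backward = bwd
        return out

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        out._backward = bwd
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, 1.0) * g)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


# ----------------------------------------------------------------------
# free functions


def exp(t: Tensor) -> Tensor:
    out = Tensor(np.exp(t.data), parents=(t,))

    def bwd(g):
        if t.requires_grad:
            t._accum(g * out.data)

    out._backward = bwd
    return out


def log(t: Tensor) -> Tensor:
    out = Tensor(np.log(t.data), parents=(t,))

    def bwd(g):
        if t.requires_grad:
            t._accum(g / t.data)

    out._backward = bwd
    return out


def sigmoid(t: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-t.data))
    out = Tensor(s, parents=(t,))

    def bwd(g):
        if t.requires_grad:
            t._accum(g * s * (1.0 - s))

    out._backward = bwd
    return out


def relu(t: Tensor) -> Tensor:
    out = Tensor(np.maximum(t.data, 0.0), parents=(t,))

    def bwd(g):
        if t.requires_grad:
            t._accum(g * (t.data > 0.0))

    out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bwd
    return out


def take_rows(t: Tensor, idx) -> Tensor:
    """Gather rows (or elements for 1-D input) by integer index."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(t.data[idx], parents=(t,))

    def bwd(g):
        if t.requires_grad:
            acc = np.zeros_like(t.data)
            np.add.at(acc, idx, g)
            t._accum(acc)

    out._backward = bwd
    return out


def span_max(t: Tensor, spans) -> Tensor:
    """Per-span columnwise max over rows s..e (0-based inclusive pairs)."""
    n, d = len(spans), t.data.shape[1]
    out_data = np.empty((n, d))
    argmax = np.empty((n, d), dtype=np.intp)
    for i, (s, e) in enumerate(spans):
        seg = t.data[s : e + 1]
        am = seg.argmax(axis=0)
        argmax[i] = am + s
        out_data[i] = seg[am, np.arange(d)]
    out = Tensor(out_data, parents=(t,))
    cols = np.arange(d)

    def bwd(g):
        if t.requires_grad:
            acc = np.zeros_like(t.data)
            for i in range(n):
                np.add.at(acc, (argmax[i], cols), g[i])
            t._accum(acc)

    out._backward = bwd
    return out


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    z = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(p, parents=(t,))

    def bwd(g):
        if t.requires_grad:
            dot = (g * p).sum(axis=axis, keepdims=True)
            t._accum(p * (g - dot))

    out._backward = bwd
    return out


def masked_softmax(t: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Row softmax restricted to `mask`; all-masked rows yield zero rows."""
    mask = np.asarray(mask, dtype=bool)
    neg = np.where(mask, t.data, -np.inf)
    mx = neg.max(axis=axis, keepdims=True)
    mx = np.where(np.isfinite(mx), mx, 0.0)
    e = np.where(mask, np.exp(neg - mx), 0.0)
    denom = e.sum(axis=axis, keepdims=True)
    p = np.divide(e, denom, out=np.zeros_like(e), where=denom > 0)
    out = Tensor(p, parents=(t,))

    def bwd(g):
        if t.requires_grad:
            dot = (g * p).sum(axis=axis, keepdims=True)
            t._accum(p * (g - dot))

    out._backward = bwd
    return out


def layer_norm(t: Tensor, eps: float = 1e-5) -> Tensor:
    """Parameter-free layer normalisation over the last axis."""
    mu = t.data.mean(axis=-1, keepdims=True)
    xc = t.data - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = xc * inv
    out = Tensor(y, parents=(t,))
    d = t.data.shape[-1]

    def bwd(g):
        if t.requires_grad:
            gm = g.mean(axis=-1, keepdims=True)
            gy = (g * y).mean(axis=-1, keepdims=True)
            t._accum(inv * (g - gm - y * gy))

    out._backward = bwd
    return out
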
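"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains small models (gated-attention pooling, degree-scaled
message passing, linear heads) whose parameter counts are in the tens of
thousands, so a compact tape-based engine in double precision is adequate
and keeps every computation deterministic under a fixed seed.

Only the operations the models actually use are implemented.  Gradients
are accumulated densely; broadcasting in elementwise ops is undone by
summing over broadcast axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "segment_extreme",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient tape entry."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = tuple(parents)
        self._backward = backward
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in self._parents
        )

    # -- bookkeeping ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from a scalar tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -----------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bwd(g, a=self):
            if a.requires_grad:
                a._accumulate(g * e * a.data ** (e - 1.0))

        return Tensor(self.data ** e, (self,), bwd)

    # -- linear algebra ---------------------------------------------------
    def __matmul__(self, other):
        other = self._coerce(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)

        return Tensor(self.data @ other.data, (self, other), bwd)

    @property
    def T(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accumulate(g.T)

        return Tensor(self.data.T, (self,), bwd)

    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g, a=self):
            if a.requires_grad:
                a._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(*shape), (self,), bwd)

    def rows(self, index) -> "Tensor":
        """Select rows by integer index array (gather along axis 0)."""
        index = np.asarray(index, dtype=np.intp)

        def bwd(g, a=self):
            if a.requires_grad:
                out = np.zeros_like(a.data)
                np.add.at(out, index, g)
                a._accumulate(out)

        return Tensor(self.data[index], (self,), bwd)

    # -- nonlinearities ---------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g, a=self, o=out_data):
            if a.requires_grad:
                a._accumulate(g * o)

        return Tensor(out_data, (self,), bwd)

    def log(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return Tensor(np.log(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g, a=self, o=out_data):
            if a.requires_grad:
                a._accumulate(g / (2.0 * np.maximum(o, 1e-300)))

        return Tensor(out_data, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g, a=self, o=out_data):
            if a.requires_grad:
                a._accumulate(g * (1.0 - o * o))

        return Tensor(out_data, (self,), bwd)

    def sigmoid(self):
        from scipy.special import expit

        out_data = expit(self.data)

        def bwd(g, a=self, o=out_data):
            if a.requires_grad:
                a._accumulate(g * o * (1.0 - o))

        return Tensor(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g, a=self, m=mask):
            if a.requires_grad:
                a._accumulate(g * m)

        return Tensor(self.data * mask, (self,), bwd)

    def clip_min(self, lo: float):
        """Elementwise max(x, lo); gradient passes only where x > lo."""
        mask = self.data > lo

        def bwd(g, a=self, m=mask):
            if a.requires_grad:
                a._accumulate(g * m)

        return Tensor(np.maximum(self.data, lo), (self,), bwd)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g, a=self):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g, a=self, s=s):
            if a.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                a._accumulate((g - dot) * s)

        return Tensor(s, (self,), bwd)


class Parameter(Tensor):
    """A leaf tensor updated by an optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g, ts=tensors, off=offsets):
        for t, lo, hi in zip(ts, off[:-1], off[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd)


def segment_extreme(values: Tensor, segment_ids, num_segments: int, mode: str) -> Tensor:
    """Per-segment max or min over rows of ``values``.

    Rows of ``values`` belong to segments given by ``segment_ids``; empty
    segments yield zero rows (the caller masks them out).  The gradient
    routes to the arg-extreme row of each segment, first occurrence on ties.
    """
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    seg = np.asarray(segment_ids, dtype=np.intp)
    data = values.data
    out = np.zeros((num_segments, data.shape[1]))
    argrows = np.full((num_segments, data.shape[1]), -1, dtype=np.intp)
    order = np.argsort(seg, kind="stable")
    cmp = np.greater if mode == "max" else np.less
    for r in order:
        s = seg[r]
        if argrows[s, 0] < 0:
            out[s] = data[r]
            argrows[s] = r
        else:
            better = cmp(data[r], out[s])
            out[s] = np.where(better, data[r], out[s])
            argrows[s] = np.where(better, r, argrows[s])

    def bwd(g, v=values, arg=argrows):
        if not v.requires_grad:
            return
        grad = np.zeros_like(v.data)
        for s in range(num_segments):
            if arg[s, 0] < 0:
                continue
            for j in range(g.shape[1]):
                grad[arg[s, j], j] += g[s, j]
        v._accumulate(grad)

    return Tensor(out, (values,), bwd)
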
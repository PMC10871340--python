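"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is a small, self-contained tensor library: a :class:`Tensor` wraps a
numpy array and records the operations applied to it so that
:meth:`Tensor.backward` can accumulate gradients by reverse topological
traversal.  It supports exactly the operations needed by the transformer
models in this package (broadcasting elementwise arithmetic, batched
matmul, reductions, slicing, concatenation and the usual nonlinearities).
Float32 is used throughout for speed on CPU.

Inside a :func:`no_grad` block no graph is recorded, which makes inference
allocation-light.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "concatenate",
    "fused_layer_norm",
    "fused_gelu",
    "fused_softmax",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to produce it."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- graph bookkeeping -------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            return Tensor(data, requires_grad=True, parents=parents, backward=backward)
        return Tensor(data)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float32)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                # leaf: accumulate into .grad
                node.grad = g if node.grad is None else node.grad + g
            else:
                node._backward(g, grads)

    # -- elementwise arithmetic -------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def bwd(g, grads):
            _accum(grads, self, _unbroadcast(g, self.shape))
            _accum(grads, other, _unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)

        def bwd(g, grads):
            _accum(grads, self, _unbroadcast(g * other.data, self.shape))
            _accum(grads, other, _unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        def bwd(g, grads):
            _accum(grads, self, -g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)

        def bwd(g, grads):
            _accum(grads, self, _unbroadcast(g / other.data, self.shape))
            _accum(
                grads,
                other,
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def bwd(g, grads):
            _accum(grads, self, g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), bwd)

    # -- matmul ------------------------------------------------------------

    def __matmul__(self, other):
        other = self._wrap(other)

        def bwd(g, grads):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                _accum(grads, self, _unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                _accum(grads, other, _unbroadcast(gb, other.shape))

        return self._make(np.matmul(self.data, other.data), (self, other), bwd)

    # -- nonlinearities ----------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g, grads):
            _accum(grads, self, g * out_data)

        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g, grads):
            _accum(grads, self, g / self.data)

        return self._make(np.log(self.data), (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g, grads):
            _accum(grads, self, g * (1.0 - out_data**2))

        return self._make(out_data, (self,), bwd)

    def sin(self):
        def bwd(g, grads):
            _accum(grads, self, g * np.cos(self.data))

        return self._make(np.sin(self.data), (self,), bwd)

    def cos(self):
        def bwd(g, grads):
            _accum(grads, self, -g * np.sin(self.data))

        return self._make(np.cos(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g, grads):
            _accum(grads, self, g / (2.0 * out_data))

        return self._make(out_data, (self,), bwd)

    # -- reductions / shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g, grads):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            _accum(grads, self, np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g, grads):
            _accum(grads, self, g.reshape(self.shape))

        return self._make(self.data.reshape(shape), (self,), bwd)

    def swapaxes(self, a: int, b: int):
        def bwd(g, grads):
            _accum(grads, self, np.swapaxes(g, a, b))

        return self._make(np.swapaxes(self.data, a, b), (self,), bwd)

    def __getitem__(self, idx):
        items = idx if isinstance(idx, tuple) else (idx,)
        basic = all(
            isinstance(i, (slice, int)) or i is None or i is Ellipsis
            for i in items
        )

        def bwd(g, grads):
            full = np.zeros(self.shape, dtype=np.float32)
            if basic:  # no duplicate indices possible: plain accumulation
                full[idx] += g
            else:  # fancy indexing may repeat entries (e.g. embedding lookup)
                np.add.at(full, idx, g)
            _accum(grads, self, full)

        return self._make(self.data[idx], (self,), bwd)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _accum(grads: dict, node: Tensor, g: np.ndarray) -> None:
    if not node.requires_grad:
        return
    key = id(node)
    if node._backward is None:
        node.grad = g if node.grad is None else node.grad + g
        return
    if key in grads:
        grads[key] = grads[key] + g
    else:
        grads[key] = g


def fused_layer_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance (no affine)."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = xc * inv

    def bwd(g, grads):
        gy = g * inv
        gx = gy - gy.mean(axis=-1, keepdims=True) - y * (
            (gy * y).mean(axis=-1, keepdims=True)
        )
        _accum(grads, x, gx.astype(np.float32))

    return Tensor._make(y, (x,), bwd)


_GELU_C = 0.7978845608028654  # sqrt(2/pi)


def fused_gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation), fused backward."""
    xd = x.data
    x2 = xd * xd
    inner = _GELU_C * (xd + 0.044715 * (x2 * xd))
    t = np.tanh(inner)
    y = 0.5 * xd * (1.0 + t)

    def bwd(g, grads):
        dinner = _GELU_C * (1.0 + 3 * 0.044715 * x2)
        dy = 0.5 * (1.0 + t) + 0.5 * xd * (1.0 - t * t) * dinner
        _accum(grads, x, (g * dy).astype(np.float32))

    return Tensor._make(y, (x,), bwd)


def fused_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Softmax along ``axis`` with the standard fused Jacobian product."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g, grads):
        gx = (g - (g * y).sum(axis=axis, keepdims=True)) * y
        _accum(grads, x, gx.astype(np.float32))

    return Tensor._make(y, (x,), bwd)


def concatenate(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g, grads):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            _accum(grads, t, g[tuple(sl)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor._make(data, tuple(tensors), bwd)
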
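"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients.  The op set is exactly what the two
network stages need: broadcast arithmetic, matmul (batched), 1-D
convolution and max-pooling, ReLU, exponential/power, reductions, shape
ops, concatenation and slicing.

Design notes
------------
* float64 throughout: the suite checks closed-form oracles to tight
  tolerances and the models here are small enough that speed is not an
  issue.
* Softmax & friends are composites built from these primitives (see
  :mod:`radarbp.nn.layers`), so their gradients need no special casing.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "maxpool1d"]

ArrayLike = Union[np.ndarray, float, int, Sequence]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data: ArrayLike, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: Tuple["Tensor", ...] = ()

    # -- plumbing ----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad = self.grad + g

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Accumulate d(self)/d(leaf) into every reachable leaf's ``grad``."""
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
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data) if grad is None \
            else np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data: np.ndarray, prev: Iterable["Tensor"]) -> "Tensor":
        out = Tensor(data)
        prev = tuple(p for p in prev if isinstance(p, Tensor))
        out.requires_grad = any(p.requires_grad or p._prev or
                                p._backward is not None for p in prev)
        if out.requires_grad:
            out._prev = prev
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out = self._make(self.data + other.data, (self, other))

        def _bw():
            self._accum(_unbroadcast(out.grad, self.shape))
            other._accum(_unbroadcast(out.grad, other.shape))
        out._backward = _bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,))

        def _bw():
            self._accum(-out.grad)
        out._backward = _bw if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = self._make(self.data * other.data, (self, other))

        def _bw():
            self._accum(_unbroadcast(out.grad * other.data, self.shape))
            other._accum(_unbroadcast(out.grad * self.data, other.shape))
        out._backward = _bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = self._make(self.data ** exponent, (self,))

        def _bw():
            self._accum(out.grad * exponent * self.data ** (exponent - 1.0))
        out._backward = _bw if out.requires_grad else None
        return out

    def exp(self):
        out = self._make(np.exp(self.data), (self,))

        def _bw():
            self._accum(out.grad * out.data)
        out._backward = _bw if out.requires_grad else None
        return out

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        out = self._make(np.maximum(self.data, 0.0), (self,))

        def _bw():
            self._accum(out.grad * (self.data > 0))
        out._backward = _bw if out.requires_grad else None
        return out

    # -- linear algebra ----------------------------------------------------

    def __matmul__(self, other):
        other = self._lift(other)
        out = self._make(self.data @ other.data, (self, other))

        def _bw():
            go = out.grad
            ga = go @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ go
            self._accum(_unbroadcast(ga, self.shape))
            other._accum(_unbroadcast(gb, other.shape))
        out._backward = _bw if out.requires_grad else None
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def _bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())
        out._backward = _bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self._make(self.data.reshape(shape), (self,))

        def _bw():
            self._accum(out.grad.reshape(self.shape))
        out._backward = _bw if out.requires_grad else None
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = self._make(self.data.transpose(axes), (self,))
        inv = np.argsort(axes)

        def _bw():
            self._accum(out.grad.transpose(inv))
        out._backward = _bw if out.requires_grad else None
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,))

        def _bw():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accum(g)
        out._backward = _bw if out.requires_grad else None
        return out

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along an axis (differentiable)."""
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = tensors[0]._make(data, tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * data.ndim
            sl[axis] = slice(a, b)
            t._accum(out.grad[tuple(sl)])
    out._backward = _bw if out.requires_grad else None
    return out


def _cols_view(xp: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    """Sliding-window view (N, C, K, L_out) of a padded (N, C, L) array."""
    n, c, lp = xp.shape
    lo = (lp - kernel) // stride + 1
    s = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, (n, c, kernel, lo), (s[0], s[1], s[2], s[2] * stride),
        writeable=False)


def conv1d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of (N, C, L) inputs with (F, C, K) kernels."""
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding)))
    cols = _cols_view(xd, w.shape[2], stride)
    out_data = np.einsum("nckl,fck->nfl", cols, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None]
    prev = (x, w) if b is None else (x, w, b)
    out = x._make(out_data, prev)
    kernel = w.shape[2]
    lo = out_data.shape[2]

    def _bw():
        go = out.grad
        w._accum(np.einsum("nfl,nckl->fck", go, cols, optimize=True))
        if b is not None:
            b._accum(go.sum(axis=(0, 2)))
        gxp = np.zeros_like(xd)
        for k in range(kernel):
            gxp[:, :, k: k + stride * lo: stride] += np.einsum(
                "nfl,fc->ncl", go, w.data[:, :, k], optimize=True)
        if padding:
            gxp = gxp[:, :, padding: gxp.shape[2] - padding]
        x._accum(gxp)
    out._backward = _bw if out.requires_grad else None
    return out


def maxpool1d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    """Max pooling over the last axis of a (N, C, L) tensor."""
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding)),
                    constant_values=-np.inf)
    cols = _cols_view(xd, kernel, stride)
    arg = cols.argmax(axis=2)                       # (N, C, L_out)
    out_data = cols.max(axis=2)
    out = x._make(out_data, (x,))
    lo = out_data.shape[2]

    def _bw():
        go = out.grad
        gxp = np.zeros_like(xd)
        for k in range(kernel):
            mask = arg == k
            gxp[:, :, k: k + stride * lo: stride] += go * mask
        if padding:
            gxp = gxp[:, :, padding: gxp.shape[2] - padding]
        x._accum(gxp)
    out._backward = _bw if out.requires_grad else None
    return out
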
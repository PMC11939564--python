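"""Neural-network building blocks on top of the autodiff core.

Initialization draws from an explicit ``numpy.random.Generator`` so a model
is fully determined by its config and seed.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from .autodiff import Tensor, conv1d, maxpool1d

__all__ = ["Module", "Linear", "Conv1d", "BatchNorm1d", "LayerNorm", "ReLU",
           "MaxPool1d", "Sequential", "softmax", "scaled_dot_attention",
           "MultiHeadAttention", "positional_encoding", "causal_mask"]


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    training: bool = True

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        seen = set()
        for obj in self.__dict__.values():
            for p in _collect(obj):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> List["Module"]:
        mods: List[Module] = [self]
        for obj in self.__dict__.values():
            mods.extend(_collect_modules(obj))
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def state_arrays(self) -> List[np.ndarray]:
        """Parameters + buffers, in a stable order (for checkpoints)."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            for name in getattr(m, "_buffers", ()):
                arrays.append(getattr(m, name))
        return arrays

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(obj) -> List[Tensor]:
    if isinstance(obj, Tensor) and obj.requires_grad:
        return [obj]
    if isinstance(obj, Module):
        return obj.parameters()
    if isinstance(obj, (list, tuple)):
        out: List[Tensor] = []
        for o in obj:
            out.extend(_collect(o))
        return out
    return []


def _collect_modules(obj) -> List[Module]:
    if isinstance(obj, Module):
        return obj.modules()
    if isinstance(obj, (list, tuple)):
        out: List[Module] = []
        for o in obj:
            out.extend(_collect_modules(o))
        return out
    return []


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 weight_scale: Optional[float] = None, bias_init: float = 0.0):
        scale = weight_scale if weight_scale is not None \
            else np.sqrt(2.0 / in_dim)
        self.W = Tensor(rng.normal(0.0, scale, (in_dim, out_dim)),
                        requires_grad=True)
        self.b = Tensor(np.full(out_dim, bias_init, dtype=float),
                        requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Conv1d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.W = Tensor(rng.normal(0.0, scale, (out_ch, in_ch, kernel)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.W, self.b, stride=self.stride,
                      padding=self.padding)


class BatchNorm1d(Module):
    """Batch normalization over (N, C, L): statistics per channel."""

    _buffers = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean[None, :, None]
            sd = np.sqrt(self.running_var + self.eps)[None, :, None]
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xhat * self.gamma.reshape(1, -1, 1) \
            + self.beta.reshape(1, -1, 1)


class LayerNorm(Module):
    """Per-sample normalization over the last axis:
    gamma * (x - mu) / sigma + beta."""

    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        xhat = (x - mu) * (var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool1d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return maxpool1d(x, self.kernel, self.stride, self.padding)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max-shift treated as a constant)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor, d_k: int,
                         mask: Optional[np.ndarray] = None) -> Tensor:
    """softmax(Q K^T / sqrt(d_k)) V, optionally with an additive mask.

    Works on (..., T, d) stacks; the attention-weight rows sum to 1.
    """
    scores = (q @ k.transpose(*range(q.ndim - 2), q.ndim - 1, q.ndim - 2)) \
        * (1.0 / np.sqrt(d_k))
    if mask is not None:
        scores = scores + Tensor(mask)
    return softmax(scores, axis=-1) @ v


def attention_weights(q: np.ndarray, k: np.ndarray, d_k: int,
                      mask: Optional[np.ndarray] = None) -> np.ndarray:
    """The softmax weight matrix itself (diagnostics / tests)."""
    scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(d_k)
    if mask is not None:
        scores = scores + mask
    scores = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=-1, keepdims=True)


def causal_mask(t: int) -> np.ndarray:
    """Additive mask forbidding attention to future positions."""
    m = np.zeros((t, t))
    m[np.triu_indices(t, k=1)] = -1e9
    return m


class MultiHeadAttention(Module):
    """Per-head Q/K/V projections, scaled dot-product attention per head,
    concatenation, and an output projection."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model, self.h = d_model, n_heads
        self.d_k = d_model // n_heads
        scale = np.sqrt(1.0 / d_model)
        self.Wq = Linear(d_model, d_model, rng, weight_scale=scale)
        self.Wk = Linear(d_model, d_model, rng, weight_scale=scale)
        self.Wv = Linear(d_model, d_model, rng, weight_scale=scale)
        self.Wo = Linear(d_model, d_model, rng, weight_scale=scale)

    def _split(self, x: Tensor, b: int, t: int) -> Tensor:
        # (B, T, d_model) -> (B, H, T, d_k)
        return x.reshape(b, t, self.h, self.d_k).transpose(0, 2, 1, 3)

    def forward(self, q: Tensor, k: Tensor, v: Tensor,
                mask: Optional[np.ndarray] = None) -> Tensor:
        b, tq = q.shape[0], q.shape[1]
        tk = k.shape[1]
        qh = self._split(self.Wq(q), b, tq)
        kh = self._split(self.Wk(k), b, tk)
        vh = self._split(self.Wv(v), b, tk)
        heads = scaled_dot_attention(qh, kh, vh, self.d_k, mask=mask)
        merged = heads.transpose(0, 2, 1, 3).reshape(b, tq, self.d_model)
        return self.Wo(merged)


def positional_encoding(pos: int, d_model: int) -> np.ndarray:
    """Sine-cosine positional encoding row for one position.

    PE(pos, 2i) = sin(pos / 10000^(2i/d_model)),
    PE(pos, 2i+1) = cos(pos / 10000^(2i/d_model)).
    """
    if pos < 0:
        raise ValueError("pos must be >= 0")
    pe = np.empty(d_model)
    i = np.arange(0, d_model, 2)
    angle = pos / np.power(10000.0, i / d_model)
    pe[0::2] = np.sin(angle)
    pe[1::2] = np.cos(angle[: d_model // 2])
    return pe


def positional_encoding_matrix(t: int, d_model: int) -> np.ndarray:
    return np.stack([positional_encoding(p, d_model) for p in range(t)])
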
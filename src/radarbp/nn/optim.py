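"""Adam with decoupled weight decay, plus the plateau LR scheduler."""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

from .autodiff import Tensor

__all__ = ["AdamW", "PlateauScheduler"]


class AdamW:
    """Adam where the L2 penalty is applied directly to the weights
    (decoupled from the adaptive gradient moments)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params: List[Tensor] = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class PlateauScheduler:
    """Multiply the LR by ``factor`` when the monitored loss has not
    improved for ``patience`` consecutive epochs.

    With a constant loss stream the first epoch establishes the best value
    and the LR first halves at the end of epoch ``patience + 1``.
    """

    def __init__(self, optimizer: AdamW, factor: float = 0.5,
                 patience: int = 5, min_delta: float = 1e-12):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.bad_epochs = 0

    @property
    def lr(self) -> float:
        return self.opt.lr

    def step(self, loss: float) -> None:
        if loss < self.best - self.min_delta:
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.opt.lr *= self.factor
                self.bad_epochs = 0
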
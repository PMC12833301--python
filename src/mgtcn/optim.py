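"""Adam optimizer and learning-rate schedules for the NumPy network."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Adam", "cosine_lr", "PlateauScheduler"]


class Adam:
    """Adam with L2 weight decay added to the gradient (coupled form)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr(base_lr: float, epoch: int, max_epochs: int, eta_min: float = 0.0) -> float:
    """Cosine annealing from base_lr down to eta_min over max_epochs."""
    return eta_min + 0.5 * (base_lr - eta_min) * (1 + np.cos(np.pi * epoch / max(max_epochs, 1)))


class PlateauScheduler:
    """Halve the learning rate when the monitored loss stops improving."""

    def __init__(self, base_lr: float, factor: float = 0.5, patience: int = 5, min_lr: float = 1e-6):
        self.lr = base_lr
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.stale = 0

    def step(self, loss: float) -> float:
        if loss < self.best - 1e-12:
            self.best = loss
            self.stale = 0
        else:
            self.stale += 1
            if self.stale > self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self.stale = 0
        return self.lr
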
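"""Adam optimizer and the cosine learning-rate schedule used for training."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor

__all__ = ["Adam", "cosine_lr"]


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def cosine_lr(epoch: int, n_epochs: int, lr_max: float = 1e-4,
              lr_min: float = 1e-5) -> float:
    """Cosine decay from lr_max (epoch 0) to lr_min (final epoch)."""
    if n_epochs <= 1:
        return lr_max
    frac = epoch / (n_epochs - 1)
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * frac))
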
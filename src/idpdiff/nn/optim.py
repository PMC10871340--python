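"""Adam optimizer and learning-rate schedules.

Learning-rate scheduling is treated as a first-class knob here because
diffusion-model training quality depends on it strongly; the default is
linear warmup followed by cosine decay to a small floor.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .autodiff import Tensor

__all__ = ["Adam", "warmup_cosine", "constant_lr"]


def constant_lr(lr: float) -> Callable[[int], float]:
    return lambda step: lr


def warmup_cosine(
    lr: float, total_steps: int, warmup: int = 100, floor_frac: float = 0.01
) -> Callable[[int], float]:
    """Linear warmup to ``lr`` then cosine decay to ``floor_frac * lr``."""

    def schedule(step: int) -> float:
        if step < warmup:
            return lr * (step + 1) / warmup
        frac = (step - warmup) / max(total_steps - warmup, 1)
        frac = min(frac, 1.0)
        cos = 0.5 * (1.0 + np.cos(np.pi * frac))
        return lr * (floor_frac + (1.0 - floor_frac) * cos)

    return schedule


class Adam:
    def __init__(
        self,
        params: list[Tensor],
        lr: float | Callable[[int], float] = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.schedule = lr if callable(lr) else constant_lr(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.step_count = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> float:
        """One update; returns the learning rate used."""
        lr = self.schedule(self.step_count)
        self.step_count += 1
        t = self.step_count
        bc1 = 1.0 - self.b1**t
        bc2 = 1.0 - self.b2**t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * (g * g)
            m_hat = self.m[i] / bc1
            v_hat = self.v[i] / bc2
            p.data = p.data - lr * m_hat / (np.sqrt(v_hat) + self.eps)
        return lr
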
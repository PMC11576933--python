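"""Optimization: Adam with a high first-moment decay, and the cosine
learning-rate schedule with warm restarts used for all training arms.

The training recipe fixes the momentum parameter at 0.95 to compensate for
the small mini-batch size (16); here that maps onto Adam's ``beta1``.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Adam", "cosine_warm_restart_lr"]


class Adam:
    """Adam over a named parameter dict, ``beta1`` defaulting to 0.95."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.95, 0.999), eps: float = 1e-8):
        self.params = dict(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data, dtype=float) for k, p in self.params.items()}
        self._v = {k: np.zeros_like(p.data, dtype=float) for k, p in self.params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self._m[k]
            v = self._v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            step = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data = (p.data - step).astype(p.data.dtype, copy=False)


def cosine_warm_restart_lr(
    epoch: int,
    base_lr: float = 1e-3,
    t0: int = 10,
    mult: int = 2,
    eta_min: float = 1e-5,
) -> float:
    """Cosine-annealed learning rate with warm restarts.

    The first period lasts ``t0`` epochs and each subsequent period is
    ``mult`` times longer, so with the defaults restarts happen at
    cumulative epochs 10, 30, 70, ...  ``lr(0) = base_lr``.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    period = t0
    start = 0
    while epoch >= start + period:
        start += period
        period *= mult
    t = (epoch - start) / period
    return eta_min + (base_lr - eta_min) * 0.5 * (1.0 + np.cos(np.pi * t))
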
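"""SGD with momentum/weight decay and the cosine-annealing schedule."""

from __future__ import annotations

import math

import numpy as np


class SGD:
    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad.astype(p.dtype)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_lr(lr0: float, epoch: int, total_epochs: int) -> float:
    """lr(e) = lr0 * (1 + cos(pi * e / E)) / 2 — lr0 at e=0, ~0 at e=E."""
    return lr0 * (1.0 + math.cos(math.pi * epoch / total_epochs)) / 2.0
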
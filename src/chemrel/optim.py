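"""Optimizers for the autodiff parameter tensors."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class RMSProp:
    """RMSProp with the conventional moving-average denominator.

    Defaults: learning rate 1e-3, decay 0.9, epsilon 1e-7 — the same
    settings used for the relation classifier.
    """

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 decay: float = 0.9, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.decay = decay
        self.eps = eps
        self._cache = {name: np.zeros_like(p.data) for name, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        for name, p in self.params.items():
            if p.grad is None:
                continue
            c = self._cache[name]
            c *= self.decay
            c += (1.0 - self.decay) * p.grad**2
            p.data -= self.lr * p.grad / (np.sqrt(c) + self.eps)
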
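"""Adaptive-moment gradient descent (Adam) for the numpy networks."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Standard Adam with bias correction.

    Defaults follow the training recipe used throughout the package:
    learning rate 1e-4, beta1 0.9, beta2 0.999, eps 1e-8.  State is kept
    per parameter array and carried across data-regime switches.
    """

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr < 0:
            raise ValueError("learning rate must be >= 0")
        self.params = params
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= (self.lr / c1) * m / (np.sqrt(v / c2) + self.eps)
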
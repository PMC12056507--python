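"""Optimizers: Adam, rectified Adam (RAdam), and the Lookahead wrapper.

All operate in place on the model's parameter dict; the learning rate
is passed per step so the 1-cycle schedule stays outside the
optimizer.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Adam", "RAdam", "Lookahead", "make_optimizer"]


class Adam:
    def __init__(self, params: dict, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / bc1
            v_hat = self.v[k] / bc2
            p -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


class RAdam:
    """Rectified Adam: the adaptive term is variance-rectified and the
    update falls back to plain momentum SGD while the variance estimate
    is still unreliable (early steps)."""

    def __init__(self, params: dict, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.rho_inf = 2.0 / (1.0 - beta2) - 1.0

    def step(self, grads: dict, lr: float) -> None:
        self.t += 1
        b1, b2, t = self.beta1, self.beta2, self.t
        rho_t = self.rho_inf - 2.0 * t * b2**t / (1.0 - b2**t)
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**t)
            if rho_t > 4.0:
                v_hat = np.sqrt(self.v[k] / (1 - b2**t))
                r = math.sqrt(
                    (rho_t - 4) * (rho_t - 2) * self.rho_inf
                    / ((self.rho_inf - 4) * (self.rho_inf - 2) * rho_t)
                )
                p -= lr * r * m_hat / (v_hat + self.eps)
            else:
                p -= lr * m_hat


class Lookahead:
    """Lookahead wrapper: every ``k`` fast steps the slow weights move
    a fraction ``alpha`` toward the fast weights and the fast weights
    are reset to them."""

    def __init__(self, inner, params: dict, k: int = 5, alpha: float = 0.5):
        self.inner = inner
        self.params = params
        self.k = k
        self.alpha = alpha
        self.slow = {key: v.copy() for key, v in params.items()}
        self.counter = 0

    def step(self, grads: dict, lr: float) -> None:
        self.inner.step(grads, lr)
        self.counter += 1
        if self.counter % self.k == 0:
            for key, p in self.params.items():
                self.slow[key] += self.alpha * (p - self.slow[key])
                p[...] = self.slow[key]


def make_optimizer(name: str, params: dict):
    """Factory for the two supported configurations."""
    if name == "adam":
        return Adam(params)
    if name == "radam_lookahead":
        return Lookahead(RAdam(params), params)
    raise ValueError(f"unknown optimizer {name!r}; choose adam or radam_lookahead")
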
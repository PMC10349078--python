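"""Rectified Adam (RAdam) with L2 weight decay.

Implements the variance-rectified update of Liu et al.: for early steps
where the variance estimate is unreliable (rectification term r_t
undefined, rho_t <= 4) the update falls back to un-adapted momentum SGD;
afterwards the Adam step is scaled by the rectification factor.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter


class RAdam:
    def __init__(self, params: list[Parameter], lr: float = 1e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.weight_decay = float(weight_decay)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def step(self) -> None:
        self.t += 1
        t = self.t
        beta2_t = self.b2**t
        rho_t = self.rho_inf - 2.0 * t * beta2_t / (1.0 - beta2_t)
        bias1 = 1.0 - self.b1**t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            m_hat = m / bias1
            if rho_t > 4.0:
                v_hat = np.sqrt(v / (1.0 - beta2_t))
                r = np.sqrt(
                    ((rho_t - 4.0) * (rho_t - 2.0) * self.rho_inf)
                    / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho_t)
                )
                p.data = p.data - self.lr * r * m_hat / (v_hat + self.eps)
            else:
                p.data = p.data - self.lr * m_hat

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
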
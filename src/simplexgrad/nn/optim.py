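"""Adam optimizer (default moment parameters)."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict = {}
        self._v: dict = {}

    def step(self, network) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        grads = dict(network.gradients())
        for key, param in network.parameters():
            g = grads[key].astype(np.float64)
            m = self._m.get(key)
            v = self._v.get(key)
            if m is None:
                m = np.zeros_like(g)
                v = np.zeros_like(g)
            m = self.beta1 * m + (1 - self.beta1) * g
            v = self.beta2 * v + (1 - self.beta2) * g * g
            self._m[key], self._v[key] = m, v
            update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            param -= update.astype(param.dtype)
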
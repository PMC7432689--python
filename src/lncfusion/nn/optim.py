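"""Adam optimizer over Sequential parameter trees."""

from __future__ import annotations

import numpy as np

from .layers import Sequential


class Adam:
    def __init__(self, net: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        """Apply one update from the gradients accumulated by backward().

        Parameters owned by non-trainable (frozen) layers are skipped.
        """
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for name, layer, key in self.net.named_params():
            if not layer.trainable or key not in layer.grads:
                continue
            g = layer.grads[key]
            m = self._m.setdefault(name, np.zeros_like(g))
            v = self._v.setdefault(name, np.zeros_like(g))
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            layer.params[key] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
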
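"""Optimizers and the reduce-on-plateau learning-rate schedule."""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, lr: float) -> None:
        self.lr = lr
        self._state: dict[int, dict[str, np.ndarray]] = {}

    def step(self, layers) -> None:
        """Apply one update to every (param, grad) pair in ``layers``."""
        for layer in layers:
            for leaf in _leaves(layer):
                state = self._state.setdefault(id(leaf), {})
                for name, p in leaf.params.items():
                    g = leaf.grads.get(name)
                    if g is None:
                        continue
                    self._update(p, g.astype(p.dtype), state, name)

    def _update(self, p, g, state, name) -> None:
        raise NotImplementedError


def _leaves(layer):
    subs = layer.sublayers
    if not subs:
        yield layer
        return
    for sub in subs:
        yield from _leaves(sub)


class RMSprop(Optimizer):
    """Keeps a running average of squared gradients (Hinton's RMSprop)."""

    def __init__(self, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-7) -> None:
        super().__init__(lr)
        self.rho = rho
        self.eps = eps

    def _update(self, p, g, state, name) -> None:
        v = state.setdefault("v_" + name, np.zeros_like(p))
        v *= self.rho
        v += (1 - self.rho) * g * g
        p -= self.lr * g / (np.sqrt(v) + self.eps)


class Adam(Optimizer):
    def __init__(
        self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8
    ) -> None:
        super().__init__(lr)
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0

    def step(self, layers) -> None:
        self.t += 1
        super().step(layers)

    def _update(self, p, g, state, name) -> None:
        m = state.setdefault("m_" + name, np.zeros_like(p))
        v = state.setdefault("v_" + name, np.zeros_like(p))
        m *= self.beta1
        m += (1 - self.beta1) * g
        v *= self.beta2
        v += (1 - self.beta2) * g * g
        mhat = m / (1 - self.beta1**self.t)
        vhat = v / (1 - self.beta2**self.t)
        p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Divide the learning rate by ``1/factor`` when val loss stalls.

    ``factor`` is the division factor (10 means lr -> lr/10) applied after
    ``patience`` consecutive epochs without improvement beyond ``min_delta``.
    """

    def __init__(
        self,
        optimizer: Optimizer,
        factor: float = 10.0,
        patience: int = 3,
        min_delta: float = 1e-4,
        min_lr: float = 1e-6,
    ) -> None:
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.min_lr = min_lr
        self.best = np.inf
        self.wait = 0

    def update(self, val_loss: float) -> bool:
        """Record an epoch's val loss; returns True if the lr was reduced."""
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.wait = 0
            return False
        self.wait += 1
        if self.wait >= self.patience and self.optimizer.lr > self.min_lr:
            self.optimizer.lr = max(self.optimizer.lr / self.factor, self.min_lr)
            self.wait = 0
            return True
        return False
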
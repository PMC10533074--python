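"""First-order optimizers matching the four optimizer genes."""

from __future__ import annotations

import numpy as np

from ..genome import OPTIMIZER_NAMES


class Optimizer:
    def __init__(self, lr: float):
        self.lr = lr
        self._state: dict[int, dict] = {}
        self._t = 0

    def _slot(self, p) -> dict:
        s = self._state.get(id(p))
        if s is None:
            s = self._init_slot(p)
            self._state[id(p)] = s
        return s

    def _init_slot(self, p) -> dict:
        return {}

    def step(self, params) -> None:
        self._t += 1
        for p in params:
            self._update(p, self._slot(p))

    def _update(self, p, slot) -> None:  # pragma: no cover
        raise NotImplementedError


class SGD(Optimizer):
    def _update(self, p, slot):
        p.value -= self.lr * p.grad


class RMSprop(Optimizer):
    def __init__(self, lr, rho=0.9, eps=1e-7):
        super().__init__(lr)
        self.rho, self.eps = rho, eps

    def _init_slot(self, p):
        return {"v": np.zeros_like(p.value)}

    def _update(self, p, slot):
        v = slot["v"]
        v *= self.rho
        v += (1 - self.rho) * p.grad**2
        p.value -= self.lr * p.grad / (np.sqrt(v) + self.eps)


class Adam(Optimizer):
    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def _init_slot(self, p):
        return {"m": np.zeros_like(p.value), "v": np.zeros_like(p.value)}

    def _update(self, p, slot):
        m, v = slot["m"], slot["v"]
        m *= self.beta1
        m += (1 - self.beta1) * p.grad
        v *= self.beta2
        v += (1 - self.beta2) * p.grad**2
        mhat = m / (1 - self.beta1**self._t)
        vhat = v / (1 - self.beta2**self._t)
        p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Adamax(Adam):
    def _update(self, p, slot):
        m, v = slot["m"], slot["v"]
        m *= self.beta1
        m += (1 - self.beta1) * p.grad
        np.maximum(self.beta2 * v, np.abs(p.grad), out=v)
        mhat = m / (1 - self.beta1**self._t)
        p.value -= self.lr * mhat / (v + self.eps)


_BY_NAME = {"sgd": SGD, "rmsprop": RMSprop, "adam": Adam, "adamax": Adamax}


def make_optimizer(code_or_name, lr: float) -> Optimizer:
    """Build an optimizer from a gene code (1-4) or its name."""
    name = (
        OPTIMIZER_NAMES[code_or_name]
        if isinstance(code_or_name, (int, np.integer))
        else str(code_or_name)
    )
    try:
        return _BY_NAME[name](lr)
    except KeyError as exc:
        raise ValueError(f"unknown optimizer {code_or_name!r}") from exc
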
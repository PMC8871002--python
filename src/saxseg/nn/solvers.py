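"""Mini-batch solvers: SGD with momentum, Adam, RMSProp.

State is keyed by parameter name and updated in place on the arrays the
network hands out, so one solver instance tracks one network.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Solver", "SGDM", "Adam", "RMSProp", "make_solver"]


class Solver:
    def __init__(self, learning_rate: float):
        if learning_rate < 0:
            raise ValueError("learning rate must be non-negative")
        self.lr = learning_rate
        self.state: dict[str, dict[str, np.ndarray]] = {}
        self.t = 0

    def step(self, params: list[tuple[str, np.ndarray, np.ndarray]]) -> None:
        self.t += 1
        for name, value, grad in params:
            st = self.state.setdefault(name, self._init_state(value))
            value -= self._update(st, grad.astype(value.dtype))

    def _init_state(self, value: np.ndarray) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def _update(self, st: dict[str, np.ndarray], grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class SGDM(Solver):
    def __init__(self, learning_rate: float, momentum: float = 0.9):
        super().__init__(learning_rate)
        self.momentum = momentum

    def _init_state(self, value):
        return {"v": np.zeros_like(value)}

    def _update(self, st, grad):
        st["v"] = self.momentum * st["v"] + grad
        return self.lr * st["v"]


class Adam(Solver):
    def __init__(self, learning_rate: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        super().__init__(learning_rate)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def _init_state(self, value):
        return {"m": np.zeros_like(value), "v": np.zeros_like(value)}

    def _update(self, st, grad):
        st["m"] = self.beta1 * st["m"] + (1 - self.beta1) * grad
        st["v"] = self.beta2 * st["v"] + (1 - self.beta2) * grad * grad
        mhat = st["m"] / (1 - self.beta1**self.t)
        vhat = st["v"] / (1 - self.beta2**self.t)
        return self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSProp(Solver):
    def __init__(self, learning_rate: float, decay: float = 0.99, eps: float = 1e-8):
        super().__init__(learning_rate)
        self.decay, self.eps = decay, eps

    def _init_state(self, value):
        return {"v": np.zeros_like(value)}

    def _update(self, st, grad):
        st["v"] = self.decay * st["v"] + (1 - self.decay) * grad * grad
        return self.lr * grad / (np.sqrt(st["v"]) + self.eps)


SOLVERS = {"sgdm": SGDM, "adam": Adam, "rmsprop": RMSProp}


def make_solver(name: str, learning_rate: float, **kwargs) -> Solver:
    try:
        cls = SOLVERS[name]
    except KeyError:
        raise ValueError(f"unknown solver {name!r}; choose from {sorted(SOLVERS)}") from None
    return cls(learning_rate, **kwargs)
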
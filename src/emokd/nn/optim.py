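"""First-order optimizers over named parameter dictionaries."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

ParamDict = dict[str, Tensor]

__all__ = ["Adam", "SGD", "clone_params", "params_fingerprint"]


def clone_params(params: ParamDict) -> ParamDict:
    return {k: Tensor(v.data.copy(), requires_grad=v.requires_grad) for k, v in params.items()}


def params_fingerprint(params: ParamDict) -> int:
    """Order-independent content hash; used for phase-purity assertions."""
    h = 0
    for k in sorted(params):
        h ^= hash((k, params[k].data.tobytes()))
    return h


class SGD:
    def __init__(self, lr: float = 1e-2):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.lr = lr

    def step(self, params: ParamDict, grads: dict[str, Tensor]) -> None:
        for k, g in grads.items():
            params[k].data -= self.lr * g.data


class Adam:
    """Adam with bias correction (beta1=0.9, beta2=0.999 defaults)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def snapshot(self) -> dict:
        return {
            "t": self.t,
            "m": {k: v.copy() for k, v in self._m.items()},
            "v": {k: v.copy() for k, v in self._v.items()},
        }

    def restore(self, snap: dict) -> None:
        self.t = snap["t"]
        self._m = {k: v.copy() for k, v in snap["m"].items()}
        self._v = {k: v.copy() for k, v in snap["v"].items()}

    def step(self, params: ParamDict, grads: dict[str, Tensor]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in sorted(grads):
            g = grads[k].data
            m = self._m.setdefault(k, np.zeros_like(g))
            v = self._v.setdefault(k, np.zeros_like(g))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            params[k].data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
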
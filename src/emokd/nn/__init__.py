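"""Minimal tensor autodiff engine (double-backward capable) and optimizers."""

from .autodiff import (
    Tensor,
    as_tensor,
    concatenate,
    enable_grad,
    exp,
    grad,
    log,
    no_grad,
    relu,
    sigmoid,
    tanh,
)
from .functional import (
    attention_weights,
    clip_min,
    dropout,
    layer_norm,
    linear,
    log_softmax,
    mean_pool,
    one_hot,
    scaled_dot_attention,
    sinusoidal_positions,
    softmax,
)
from .optim import SGD, Adam, ParamDict, clone_params, params_fingerprint

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "enable_grad",
    "exp",
    "grad",
    "log",
    "no_grad",
    "relu",
    "sigmoid",
    "tanh",
    "attention_weights",
    "clip_min",
    "dropout",
    "layer_norm",
    "linear",
    "log_softmax",
    "mean_pool",
    "one_hot",
    "scaled_dot_attention",
    "sinusoidal_positions",
    "softmax",
    "SGD",
    "Adam",
    "ParamDict",
    "clone_params",
    "params_fingerprint",
    "finite_difference_grad",
]


def finite_difference_grad(f, params: ParamDict, keys=None, eps: float = 1e-6) -> dict:
    """Central finite-difference gradient of scalar ``f(params)``.

    Independent numerical check used by the test-suite gradient audits; it
    never calls the reverse-mode machinery.
    """
    import numpy as np

    keys = list(params) if keys is None else list(keys)
    out = {}
    for k in keys:
        arr = params[k].data
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            old = arr[idx]
            arr[idx] = old + eps
            fp = float(f(params))
            arr[idx] = old - eps
            fm = float(f(params))
            arr[idx] = old
            g[idx] = (fp - fm) / (2 * eps)
            it.iternext()
        out[k] = g
    return out
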
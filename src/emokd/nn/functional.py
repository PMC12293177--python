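"""Composite neural operations built on the autodiff primitives.

Everything here is expressed in terms of :mod:`emokd.nn.autodiff` primitives,
so all composites are differentiable to arbitrary order.
"""

from __future__ import annotations

import numpy as np

from .autodiff import (
    Tensor,
    as_tensor,
    concatenate,
    exp,
    log,
    matmul,
    relu,
    sigmoid,
    tsum,
    where_mask,
)

__all__ = [
    "linear",
    "softmax",
    "log_softmax",
    "layer_norm",
    "dropout",
    "scaled_dot_attention",
    "clip_min",
    "mean_pool",
    "sinusoidal_positions",
]


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    out = matmul(x, w)
    if b is not None:
        out = out + b
    return out


def clip_min(x: Tensor, lo: float) -> Tensor:
    x = as_tensor(x)
    return where_mask(x.data < lo, Tensor(np.full(x.shape, lo)), x)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    # max-shift for stability; the shift is a constant w.r.t. the graph,
    # which leaves the softmax value and its derivatives unchanged
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = exp(x - shift)
    return e / tsum(e, axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - log(tsum(exp(z), axis=axis, keepdims=True))


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + eps) ** -0.5 * gamma + beta


def dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rng is None (evaluation mode)."""
    if rng is None or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p).astype(np.float64) / (1.0 - p)
    return x * Tensor(keep)


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """softmax(q k^T / sqrt(d_k)) v over the last two axes.

    Accepts [..., T, d_k] stacks; attention rows are probability vectors.
    """
    d_k = q.shape[-1]
    scores = matmul(q, k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    return matmul(softmax(scores, axis=-1), v)


def attention_weights(q: Tensor, k: Tensor) -> Tensor:
    d_k = q.shape[-1]
    return softmax(matmul(q, k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k)), axis=-1)


def mean_pool(x: Tensor, axis: int = -2) -> Tensor:
    """Average over the sequence axis of [..., T, d] features."""
    return x.mean(axis=axis)


def sinusoidal_positions(n_positions: int, d_model: int) -> np.ndarray:
    """Fixed sine/cosine position encodings (interleaved pairs)."""
    pos = np.arange(n_positions)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angles = pos / np.power(10000.0, 2.0 * i / d_model)
    pe = np.zeros((n_positions, d_model))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels.astype(int)] = 1.0
    return out
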
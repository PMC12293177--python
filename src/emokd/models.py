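"""Shared neural building blocks: convolutional frontend and transformer encoder.

The frontend follows the established two-stage biosignal pattern: a temporal
convolution with kernel (1, fs/2) — here with stride equal to the kernel, so
each half-second patch is embedded independently — followed by a spatial
convolution with kernel (channels, 1) that collapses the electrode axis into
the model width. With stride = kernel both stages reduce to reshapes and
affine maps, which keeps the computation exact and fast in the autodiff
engine. A 4 s segment at 128 Hz therefore becomes a sequence of 8 embedded
time-steps.

The encoder is a standard pre-activation-free (post-LN) transformer stack;
every layer's output is returned so fusion taps can be drawn from arbitrary
depths.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import (
    ParamDict,
    Tensor,
    concatenate,
    dropout,
    layer_norm,
    linear,
    relu,
    sinusoidal_positions,
    softmax,
)
from .nn.autodiff import matmul

__all__ = [
    "FrontendConfig",
    "EncoderConfig",
    "init_frontend",
    "conv_frontend",
    "init_encoder",
    "encode_stream",
    "glorot",
    "frontend_out_len",
]


class ConfigurationError(ValueError):
    pass


def glorot(rng: np.random.Generator, m: int, n: int) -> Tensor:
    s = np.sqrt(6.0 / (m + n))
    return Tensor(rng.uniform(-s, s, size=(m, n)), requires_grad=True)


def zeros(n: int) -> Tensor:
    return Tensor(np.zeros(n), requires_grad=True)


@dataclasses.dataclass(frozen=True)
class FrontendConfig:
    """Two-stage convolutional embedding of a [channels x samples] block."""

    n_channels: int
    fs: float = 128.0
    temporal_kernel: int | None = None  # defaults to fs / 2
    n_temporal_maps: int = 8
    d_model: int = 256
    dropout: float = 0.25

    def __post_init__(self):
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigurationError("dropout must lie in [0, 1)")

    @property
    def kernel(self) -> int:
        return int(self.fs // 2) if self.temporal_kernel is None else self.temporal_kernel


@dataclasses.dataclass(frozen=True)
class EncoderConfig:
    d_model: int = 256
    n_layers: int = 2
    n_heads: int = 4
    d_ff: int = 512
    use_positions: bool = True

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ConfigurationError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}"
            )

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads


def frontend_out_len(n_samples: int, cfg: FrontendConfig) -> int:
    return n_samples // cfg.kernel


# ---------------------------------------------------------------------------
# frontend
# ---------------------------------------------------------------------------


def init_frontend(cfg: FrontendConfig, rng: np.random.Generator, prefix: str) -> ParamDict:
    # small positive bias init keeps rectified units alive and keeps
    # pre-activations off the exact ReLU kink for fully-suppressed steps
    k, f, c, d = cfg.kernel, cfg.n_temporal_maps, cfg.n_channels, cfg.d_model
    return {
        f"{prefix}.w1": glorot(rng, k, f),
        f"{prefix}.b1": Tensor(np.full(f, 1e-2), requires_grad=True),
        f"{prefix}.w2": glorot(rng, c * f, d),
        f"{prefix}.b2": Tensor(np.full(d, 1e-2), requires_grad=True),
    }


def conv_frontend(
    x, params: ParamDict, prefix: str, cfg: FrontendConfig,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Embed [B, channels, samples] into a [B, time-steps, d_model] sequence.

    ``rng`` enables dropout (training mode); None means evaluation mode.
    """
    x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
    b, c, t = x.shape
    if c != cfg.n_channels:
        raise ConfigurationError(f"expected {cfg.n_channels} channels, got {c}")
    k = cfg.kernel
    if t < k:
        raise ConfigurationError(f"input length {t} shorter than temporal kernel {k}")
    n_steps = t // k
    if n_steps * k != t:
        x = x[:, :, : n_steps * k]
    f = cfg.n_temporal_maps
    # stage 1: temporal patches -> feature maps (kernel (1, k), stride k)
    h = x.reshape(b, c, n_steps, k)
    h = relu(linear(h, params[f"{prefix}.w1"], params[f"{prefix}.b1"]))  # [B,C,S,f]
    h = dropout(h, cfg.dropout, rng)
    # stage 2: spatial collapse (kernel (C, 1)) mixing channels x maps -> d
    h = h.transpose(0, 2, 1, 3).reshape(b, n_steps, c * f)
    h = relu(linear(h, params[f"{prefix}.w2"], params[f"{prefix}.b2"]))  # [B,S,d]
    return dropout(h, cfg.dropout, rng)


# ---------------------------------------------------------------------------
# transformer encoder
# ---------------------------------------------------------------------------


def init_encoder(cfg: EncoderConfig, rng: np.random.Generator, prefix: str) -> ParamDict:
    d, ff = cfg.d_model, cfg.d_ff
    params: ParamDict = {}
    for layer in range(cfg.n_layers):
        p = f"{prefix}.l{layer}"
        for name in ("wq", "wk", "wv", "wo"):
            params[f"{p}.{name}"] = glorot(rng, d, d)
            params[f"{p}.b{name[1]}"] = zeros(d)
        params[f"{p}.ln1.g"] = Tensor(np.ones(d), requires_grad=True)
        params[f"{p}.ln1.b"] = zeros(d)
        params[f"{p}.ff.w1"] = glorot(rng, d, ff)
        params[f"{p}.ff.b1"] = zeros(ff)
        params[f"{p}.ff.w2"] = glorot(rng, ff, d)
        params[f"{p}.ff.b2"] = zeros(d)
        params[f"{p}.ln2.g"] = Tensor(np.ones(d), requires_grad=True)
        params[f"{p}.ln2.b"] = zeros(d)
    return params


def _multi_head_attention(
    seq: Tensor, params: ParamDict, p: str, cfg: EncoderConfig,
    attention_sink: list | None = None,
) -> Tensor:
    b, t, d = seq.shape
    h, dk = cfg.n_heads, cfg.d_k

    def split_heads(x):
        return x.reshape(b, t, h, dk).transpose(0, 2, 1, 3)  # [B,h,T,dk]

    q = split_heads(linear(seq, params[f"{p}.wq"], params[f"{p}.bq"]))
    k = split_heads(linear(seq, params[f"{p}.wk"], params[f"{p}.bk"]))
    v = split_heads(linear(seq, params[f"{p}.wv"], params[f"{p}.bv"]))
    scores = matmul(q, k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dk))
    attn = softmax(scores, axis=-1)
    if attention_sink is not None:
        attention_sink.append(attn.data.copy())
    out = matmul(attn, v)  # [B,h,T,dk]
    out = out.transpose(0, 2, 1, 3).reshape(b, t, d)
    return linear(out, params[f"{p}.wo"], params[f"{p}.bo"])


def encode_stream(
    seq: Tensor, params: ParamDict, prefix: str, cfg: EncoderConfig,
    add_positions: bool | None = None,
    attention_sink: list | None = None,
) -> list[Tensor]:
    """Run the encoder stack; returns every layer's output sequence."""
    if seq.shape[-1] != cfg.d_model:
        raise ConfigurationError(f"sequence width {seq.shape[-1]} != d_model {cfg.d_model}")
    if add_positions is None:
        add_positions = cfg.use_positions
    if add_positions:
        pe = sinusoidal_positions(seq.shape[-2], cfg.d_model)
        seq = seq + Tensor(pe[None, :, :])
    outputs = []
    for layer in range(cfg.n_layers):
        p = f"{prefix}.l{layer}"
        att = _multi_head_attention(seq, params, p, cfg, attention_sink)
        seq = layer_norm(seq + att, params[f"{p}.ln1.g"], params[f"{p}.ln1.b"])
        ff = linear(relu(linear(seq, params[f"{p}.ff.w1"], params[f"{p}.ff.b1"])),
                    params[f"{p}.ff.w2"], params[f"{p}.ff.b2"])
        seq = layer_norm(seq + ff, params[f"{p}.ln2.g"], params[f"{p}.ln2.b"])
        outputs.append(seq)
    return outputs


def save_params(params: ParamDict, path) -> None:
    """Serialize a named parameter archive (npz)."""
    np.savez(path, **{k: v.data for k, v in params.items()})


def load_params(path) -> ParamDict:
    with np.load(path) as f:
        return {k: Tensor(f[k].copy(), requires_grad=True) for k in f.files}


def batch_indices(rng: np.random.Generator, n: int, batch_size: int):
    """Seeded shuffled minibatch index blocks covering all n samples."""
    perm = rng.permutation(n)
    for lo in range(0, n, batch_size):
        yield perm[lo : lo + batch_size]
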
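"""The multimodal teacher: dual-stream encoders with interaction fusion.

EEG and EOG each pass through their own convolutional frontend and their own
two-layer transformer encoder. The mean-pooled outputs of encoder layers 1
and 2 of each stream form the four fusion taps; interaction fusion gates the
per-depth cross-modal concatenations and sums them, and an affine + softmax
head classifies the fused feature. The teacher is strictly multimodal: both
modalities are required at every forward pass.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .gated_fusion import GatedExtractorParams, fuse_imf
from .models import (
    ConfigurationError,
    EncoderConfig,
    FrontendConfig,
    batch_indices,
    conv_frontend,
    encode_stream,
    glorot,
    init_encoder,
    init_frontend,
    zeros,
)
from .nn import ParamDict, Tensor, log_softmax, no_grad, one_hot, mean_pool, softmax
from .nn.optim import Adam, clone_params

__all__ = ["TeacherConfig", "TeacherOutput", "init_teacher", "teacher_forward", "pretrain_teacher"]


@dataclasses.dataclass(frozen=True)
class TeacherConfig:
    n_eeg_channels: int = 32
    n_eog_channels: int = 2
    fs: float = 128.0
    d_model: int = 256
    n_layers: int = 2
    n_heads: int = 4
    d_ff: int = 512
    n_temporal_maps: int = 8
    temporal_kernel: int | None = None
    dropout: float = 0.25
    n_classes: int = 2
    use_positions: bool = True

    def __post_init__(self):
        if self.n_layers < 2:
            raise ConfigurationError("teacher needs >= 2 encoder layers (two fusion taps)")

    def frontend(self, modality: str) -> FrontendConfig:
        n_ch = self.n_eeg_channels if modality == "eeg" else self.n_eog_channels
        return FrontendConfig(
            n_channels=n_ch, fs=self.fs, temporal_kernel=self.temporal_kernel,
            n_temporal_maps=self.n_temporal_maps, d_model=self.d_model, dropout=self.dropout,
        )

    def encoder(self) -> EncoderConfig:
        return EncoderConfig(
            d_model=self.d_model, n_layers=self.n_layers, n_heads=self.n_heads,
            d_ff=self.d_ff, use_positions=self.use_positions,
        )

    @property
    def fused_width(self) -> int:
        return 2 * self.d_model


@dataclasses.dataclass
class TeacherOutput:
    logits: Tensor            # [B, K]
    probabilities: Tensor     # [B, K]
    taps: dict                # {"x1_eog","x2_eog","x1_eeg","x2_eeg"} -> [B, d]
    fused: Tensor             # [B, 2d]  interaction-fusion output
    attention: dict | None = None  # modality -> list of [B, h, T, T] arrays


def init_teacher(cfg: TeacherConfig, rng: np.random.Generator) -> ParamDict:
    params: ParamDict = {}
    for mod in ("eeg", "eog"):
        params.update(init_frontend(cfg.frontend(mod), rng, f"{mod}.fe"))
        params.update(init_encoder(cfg.encoder(), rng, f"{mod}.enc"))
    d = cfg.d_model
    for name in ("ie1", "ie2"):
        params.update(GatedExtractorParams.init(2 * d, hidden=4 * d, rng=rng).to_dict(name))
    params["head.w"] = glorot(rng, cfg.fused_width, cfg.n_classes)
    params["head.b"] = zeros(cfg.n_classes)
    return params


def teacher_forward(
    params: ParamDict, eeg, eog, cfg: TeacherConfig,
    rng: np.random.Generator | None = None,
    collect_attention: bool = False,
) -> TeacherOutput:
    """Full multimodal forward pass; ``rng=None`` is evaluation mode."""
    if eeg is None or eog is None:
        raise ValueError("teacher is strictly multimodal: both EEG and EOG are required")
    enc_cfg = cfg.encoder()
    taps = {}
    attention: dict | None = {} if collect_attention else None
    for mod, block in (("eeg", eeg), ("eog", eog)):
        sink: list | None = [] if collect_attention else None
        seq = conv_frontend(block, params, f"{mod}.fe", cfg.frontend(mod), rng)
        layers = encode_stream(seq, params, f"{mod}.enc", enc_cfg, attention_sink=sink)
        taps[f"x1_{mod}"] = mean_pool(layers[0])
        taps[f"x2_{mod}"] = mean_pool(layers[1])
        if collect_attention:
            attention[mod] = sink
    fused = fuse_imf(
        taps["x1_eog"], taps["x1_eeg"], taps["x2_eog"], taps["x2_eeg"],
        GatedExtractorParams.from_dict(params, "ie1"),
        GatedExtractorParams.from_dict(params, "ie2"),
    )
    logits = fused @ params["head.w"] + params["head.b"]
    return TeacherOutput(
        logits=logits,
        probabilities=softmax(logits, axis=-1),
        taps=taps,
        fused=fused,
        attention=attention,
    )


def _ce_from_logits(logits: Tensor, y: np.ndarray, n_classes: int) -> Tensor:
    logp = log_softmax(logits, axis=-1)
    yh = Tensor(one_hot(y, n_classes))
    return -(yh * logp).sum() * (1.0 / len(y))


def pretrain_teacher(
    train_data, val_data, cfg: TeacherConfig,
    epochs: int = 15, batch_size: int = 64, lr: float = 1e-3, seed: int = 0,
    from_params: ParamDict | None = None,
    select: str = "best",
):
    """Supervised cross-entropy pretraining; returns the best-validation
    checkpoint (or the final state with ``select="final"``, for controlled
    comparisons where checkpoint selection would confound) and the per-epoch
    training log.

    ``train_data``/``val_data`` are (eeg [N,C,T], eog [N,C,T], y [N]) triples.
    """
    eeg_tr, eog_tr, y_tr = train_data
    eeg_va, eog_va, y_va = val_data
    if len(y_tr) == 0 or len(y_va) == 0:
        raise ValueError("empty train or validation partition")
    ss = np.random.SeedSequence(seed)
    init_rng, drop_rng, batch_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    params = clone_params(from_params) if from_params is not None else init_teacher(cfg, init_rng)
    opt = Adam(lr=lr)
    from .nn import grad as _grad

    history = []
    best = (None, -np.inf, np.inf)  # (params, val_acc, val_loss)
    for epoch in range(epochs):
        ep_loss, n_batches = 0.0, 0
        for idx in batch_indices(batch_rng, len(y_tr), batch_size):
            out = teacher_forward(params, eeg_tr[idx], eog_tr[idx], cfg, rng=drop_rng)
            loss = _ce_from_logits(out.logits, y_tr[idx], cfg.n_classes)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"teacher pretraining diverged (non-finite loss) at epoch {epoch}"
                )
            names = sorted(params)
            grads = _grad(loss, [params[k] for k in names])
            opt.step(params, dict(zip(names, grads)))
            ep_loss += loss.item()
            n_batches += 1
        val_loss, val_acc = evaluate_teacher(params, (eeg_va, eog_va, y_va), cfg)
        history.append(
            {"epoch": epoch, "train_loss": ep_loss / max(n_batches, 1),
             "val_loss": val_loss, "val_acc": val_acc}
        )
        if val_acc > best[1] or (val_acc == best[1] and val_loss < best[2]):
            best = (clone_params(params), val_acc, val_loss)
    if select == "final":
        return params, history
    return best[0], history


def evaluate_teacher(params: ParamDict, data, cfg: TeacherConfig, batch_size: int = 256):
    """Evaluation-mode CE loss and accuracy over a (eeg, eog, y) triple."""
    eeg, eog, y = data
    losses, correct = [], 0
    with no_grad():
        for lo in range(0, len(y), batch_size):
            sl = slice(lo, lo + batch_size)
            out = teacher_forward(params, eeg[sl], eog[sl], cfg, rng=None)
            losses.append(_ce_from_logits(out.logits, y[sl], cfg.n_classes).item() * len(y[sl]))
            correct += int((out.probabilities.data.argmax(axis=-1) == y[sl]).sum())
    return sum(losses) / len(y), correct / len(y)
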
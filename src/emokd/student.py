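"""The EOG-only student: one encoder stream, three taps, heterogeneous fusion.

The student mirrors one teacher stream (frontend + transformer encoder) but
with a three-layer stack, one fusion tap per layer. The gated heterogeneous
fusion of the three mean-pooled taps feeds the classification head, and an
affine alignment projection maps the fused feature to the teacher's fused
width so the two can be compared by the feature-matching loss. The student
never receives EEG — unimodality at inference is the point of distillation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .gated_fusion import GatedExtractorParams, fuse_hdf
from .models import (
    ConfigurationError,
    EncoderConfig,
    FrontendConfig,
    conv_frontend,
    encode_stream,
    glorot,
    init_encoder,
    init_frontend,
    zeros,
)
from .nn import ParamDict, Tensor, mean_pool, softmax

__all__ = ["StudentConfig", "StudentOutput", "init_student", "student_forward", "build_student_baseline"]


@dataclasses.dataclass(frozen=True)
class StudentConfig:
    n_eog_channels: int = 2
    fs: float = 128.0
    d_model: int = 256
    n_layers: int = 3
    n_heads: int = 4
    d_ff: int = 512
    n_temporal_maps: int = 8
    temporal_kernel: int | None = None
    dropout: float = 0.25
    n_classes: int = 2
    use_positions: bool = True
    #: width of the teacher feature the alignment projection maps onto;
    #: when equal to d_model the projection may be dropped (identity)
    teacher_width: int = 512
    align_identity: bool = False

    def __post_init__(self):
        if self.n_layers != 3:
            raise ConfigurationError("student uses exactly three encoder taps (one per layer)")
        if self.align_identity and self.teacher_width != self.d_model:
            raise ConfigurationError(
                f"identity alignment requires teacher_width == d_model "
                f"({self.teacher_width} != {self.d_model})"
            )

    def frontend(self) -> FrontendConfig:
        return FrontendConfig(
            n_channels=self.n_eog_channels, fs=self.fs, temporal_kernel=self.temporal_kernel,
            n_temporal_maps=self.n_temporal_maps, d_model=self.d_model, dropout=self.dropout,
        )

    def encoder(self) -> EncoderConfig:
        return EncoderConfig(
            d_model=self.d_model, n_layers=self.n_layers, n_heads=self.n_heads,
            d_ff=self.d_ff, use_positions=self.use_positions,
        )


@dataclasses.dataclass
class StudentOutput:
    logits: Tensor          # [B, K]
    probabilities: Tensor   # [B, K]
    taps: dict              # {"x1","x2","x3"} -> [B, d]
    fused: Tensor           # [B, d]   heterogeneous-fusion output
    aligned: Tensor         # [B, teacher_width]  feature compared to the teacher


def init_student(cfg: StudentConfig, rng: np.random.Generator) -> ParamDict:
    params: ParamDict = {}
    params.update(init_frontend(cfg.frontend(), rng, "fe"))
    params.update(init_encoder(cfg.encoder(), rng, "enc"))
    d = cfg.d_model
    for name in ("he1", "he2", "he3"):
        params.update(GatedExtractorParams.init(d, hidden=2 * d, rng=rng).to_dict(name))
    if not cfg.align_identity:
        params["align.w"] = glorot(rng, d, cfg.teacher_width)
        params["align.b"] = zeros(cfg.teacher_width)
    params["head.w"] = glorot(rng, d, cfg.n_classes)
    params["head.b"] = zeros(cfg.n_classes)
    return params


def build_student_baseline(cfg: StudentConfig, rng: np.random.Generator) -> ParamDict:
    """The static-distillation baseline student: identical architecture and
    parameter count; only the losses applied during training differ."""
    return init_student(cfg, rng)


def align_features(fused: Tensor, params: ParamDict, cfg: StudentConfig) -> Tensor:
    """Project the fused feature to the teacher's fused width."""
    if cfg.align_identity:
        return fused
    if "align.w" not in params:
        raise ConfigurationError(
            "teacher/student fused widths differ but no alignment projection is configured"
        )
    return fused @ params["align.w"] + params["align.b"]


def student_forward(
    params: ParamDict, eog, cfg: StudentConfig,
    rng: np.random.Generator | None = None,
    eeg=None,
) -> StudentOutput:
    """EOG-only forward pass; passing EEG is an error by design."""
    if eeg is not None:
        raise ValueError("the student is unimodal: it must never receive EEG")
    seq = conv_frontend(eog, params, "fe", cfg.frontend(), rng)
    layers = encode_stream(seq, params, "enc", cfg.encoder())
    taps = {f"x{i + 1}": mean_pool(layers[i]) for i in range(3)}
    fused = fuse_hdf(
        taps["x1"], taps["x2"], taps["x3"],
        GatedExtractorParams.from_dict(params, "he1"),
        GatedExtractorParams.from_dict(params, "he2"),
        GatedExtractorParams.from_dict(params, "he3"),
    )
    aligned = align_features(fused, params, cfg)
    logits = fused @ params["head.w"] + params["head.b"]
    return StudentOutput(
        logits=logits,
        probabilities=softmax(logits, axis=-1),
        taps=taps,
        fused=fused,
        aligned=aligned,
    )
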
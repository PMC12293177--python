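"""Gated feature extractors and the two fusion modules built from them.

A gated extractor scores its input with a two-layer network —
``score = sigmoid(fc2(relu(fc1(x))))`` — and multiplies the input by the
score element-wise, so every output component is a shrunken copy of the
corresponding input component (gates lie strictly in (0, 1)).

Two fusions share this primitive:

* interaction fusion (teacher side): two extractors, each fed the
  concatenation of one EOG tap with the matching EEG tap; their gated
  outputs are summed.
* heterogeneous deep fusion (student side): three extractors, one per
  encoder tap; gated outputs summed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import ParamDict, Tensor, concatenate, linear, relu, sigmoid

__all__ = ["GatedExtractorParams", "gate_scores", "gated_extract", "fuse_imf", "fuse_hdf"]


class ShapeError(ValueError):
    pass


@dataclasses.dataclass
class GatedExtractorParams:
    """Two affine maps of the scoring network: fc1 (rectified) then fc2
    (logistic). fc2's output width must equal the gated input's width."""

    w1: Tensor
    b1: Tensor
    w2: Tensor
    b2: Tensor

    def __post_init__(self):
        if self.w1.shape[1] != self.b1.shape[0] or self.w2.shape[1] != self.b2.shape[0]:
            raise ShapeError("bias widths inconsistent with weight matrices")
        if self.w1.shape[1] != self.w2.shape[0]:
            raise ShapeError(
                f"fc1 output width {self.w1.shape[1]} != fc2 input width {self.w2.shape[0]}"
            )

    @property
    def d_in(self) -> int:
        return self.w1.shape[0]

    @property
    def d_out(self) -> int:
        return self.w2.shape[1]

    @classmethod
    def init(cls, d_in: int, hidden: int | None = None, rng: np.random.Generator | None = None):
        """Glorot-initialized extractor; hidden defaults to 2 x d_in, output
        width equals d_in (required by the element-wise product)."""
        hidden = 2 * d_in if hidden is None else hidden
        rng = np.random.default_rng() if rng is None else rng

        def glorot(m, n):
            s = np.sqrt(6.0 / (m + n))
            return Tensor(rng.uniform(-s, s, size=(m, n)), requires_grad=True)

        return cls(
            w1=glorot(d_in, hidden),
            b1=Tensor(np.zeros(hidden), requires_grad=True),
            w2=glorot(hidden, d_in),
            b2=Tensor(np.zeros(d_in), requires_grad=True),
        )

    def to_dict(self, prefix: str) -> ParamDict:
        return {f"{prefix}.w1": self.w1, f"{prefix}.b1": self.b1,
                f"{prefix}.w2": self.w2, f"{prefix}.b2": self.b2}

    @classmethod
    def from_dict(cls, params: ParamDict, prefix: str) -> "GatedExtractorParams":
        return cls(params[f"{prefix}.w1"], params[f"{prefix}.b1"],
                   params[f"{prefix}.w2"], params[f"{prefix}.b2"])


def gate_scores(x: Tensor, p: GatedExtractorParams) -> Tensor:
    """sigmoid(fc2(relu(fc1(x)))); every component strictly in (0, 1)."""
    if x.shape[-1] != p.d_in:
        raise ShapeError(f"input width {x.shape[-1]} != extractor input width {p.d_in}")
    return sigmoid(linear(relu(linear(x, p.w1, p.b1)), p.w2, p.b2))


def gated_extract(x: Tensor, p: GatedExtractorParams) -> Tensor:
    """Gate the input by its own scores: scores(x) * x element-wise."""
    if p.d_out != x.shape[-1]:
        raise ShapeError(
            f"extractor output width {p.d_out} != gated input width {x.shape[-1]}; "
            "the element-wise product requires them equal"
        )
    return gate_scores(x, p) * x


def fuse_imf(
    x1_eog: Tensor, x1_eeg: Tensor, x2_eog: Tensor, x2_eeg: Tensor,
    ie1: GatedExtractorParams, ie2: GatedExtractorParams,
) -> Tensor:
    """Interaction fusion of the teacher's four encoder taps.

    Per tap depth, the EOG and EEG features are concatenated and passed
    through that depth's interaction extractor; the two gated outputs are
    summed element-wise.
    """
    widths = {t.shape[-1] for t in (x1_eog, x1_eeg, x2_eog, x2_eeg)}
    if len(widths) != 1:
        raise ShapeError(f"per-modality tap widths differ: {sorted(widths)}")
    c1 = concatenate([x1_eog, x1_eeg], axis=-1)
    c2 = concatenate([x2_eog, x2_eeg], axis=-1)
    return gated_extract(c1, ie1) + gated_extract(c2, ie2)


def fuse_hdf(
    x1: Tensor, x2: Tensor, x3: Tensor,
    he1: GatedExtractorParams, he2: GatedExtractorParams, he3: GatedExtractorParams,
) -> Tensor:
    """Heterogeneous deep fusion of the student's three encoder taps."""
    widths = {t.shape[-1] for t in (x1, x2, x3)}
    if len(widths) != 1:
        raise ShapeError(f"tap widths differ: {sorted(widths)}")
    return gated_extract(x1, he1) + gated_extract(x2, he2) + gated_extract(x3, he3)
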
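"""Metrics, paired significance testing, and the experiment drivers.

Accuracy and F1 follow the binary-confusion definitions
``(TP+TN)/(TP+TN+FP+FN)`` and ``2TP/(2TP+FP+FN)`` with class 1 (the high
rating) as the positive class. The ablation driver reproduces, at synthetic
scale, the three-variation comparison (logit-only distillation, + feature
fusion, + dynamic feedback), and the leakage driver contrasts trial-wise
against segment-shuffled splitting on the same segment pool.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .data_model import ValidationError, segments_to_arrays, split_per_subject
from .distill import (
    FeedbackSchedule,
    LossWeights,
    PartitionedData,
    run_distillation,
)
from .student import StudentConfig, student_forward
from .teacher import TeacherConfig, evaluate_teacher, pretrain_teacher
from .nn import no_grad

__all__ = [
    "ConfusionCounts",
    "RunResult",
    "accuracy",
    "f1_score",
    "macro_f1",
    "confusion_from_predictions",
    "paired_ttest",
    "evaluate_model",
    "run_ablation",
    "leakage_experiment",
]


class UndefinedMetricError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValidationError("prediction/label length mismatch")
    return ConfusionCounts(
        tp=int(((y_pred == 1) & (y_true == 1)).sum()),
        tn=int(((y_pred == 0) & (y_true == 0)).sum()),
        fp=int(((y_pred == 1) & (y_true == 0)).sum()),
        fn=int(((y_pred == 0) & (y_true == 1)).sum()),
    )


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined on zero counts")
    return (c.tp + c.tn) / c.total


def f1_score(c: ConfusionCounts) -> float:
    """Positive-class F1 = 2TP / (2TP + FP + FN); 0 (with warning) when the
    positive class is absent from both predictions and labels."""
    if c.total == 0:
        raise UndefinedMetricError("F1 undefined on zero counts")
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        warnings.warn("F1 undefined (no positive labels or predictions); returning 0")
        return 0.0
    return 2 * c.tp / denom


def macro_f1(c: ConfusionCounts) -> float:
    """Unweighted mean of the per-class F1 scores (exposed alongside the
    default positive-class form)."""
    neg = ConfusionCounts(tp=c.tn, tn=c.tp, fp=c.fn, fn=c.fp)
    return 0.5 * (f1_score(c) + f1_score(neg))


def paired_ttest(scores_a, scores_b):
    """Two-sided paired t-test on matched score lists."""
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired scores must be equal-length 1-D lists")
    if len(a) < 2:
        raise ValidationError("need at least 2 paired scores")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    if np.isclose(d.std(ddof=1), 0.0):
        warnings.warn("zero-variance nonzero differences; t-test degenerate")
        return float("nan"), float("nan")
    t, p = _stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RunResult:
    dimension: str
    variation: int | str
    seed: int
    counts: ConfusionCounts
    accuracy: float
    f1: float
    predictions: np.ndarray
    labels: np.ndarray

    def to_record(self) -> dict:
        return {
            "dimension": self.dimension, "variation": self.variation, "seed": self.seed,
            "accuracy": self.accuracy, "f1": self.f1,
            "tp": self.counts.tp, "tn": self.counts.tn,
            "fp": self.counts.fp, "fn": self.counts.fn,
        }

    def to_json(self, path) -> None:
        payload = self.to_record()
        payload["predictions"] = self.predictions.tolist()
        payload["labels"] = self.labels.tolist()
        with open(path, "w") as f:
            json.dump(payload, f)


def evaluate_model(
    predict_fn, data: PartitionedData, variation=0, seed: int = 0,
    context: str = "final-eval",
) -> RunResult:
    """Aggregate test-partition confusion counts for a predictor.

    ``predict_fn(eeg, eog) -> class labels``; the test partition is read
    through the audited accessor exactly once here.
    """
    eeg, eog, y = data.arrays("test", context)
    if len(y) == 0:
        raise ValidationError("empty test partition")
    preds = np.asarray(predict_fn(eeg, eog)).astype(int)
    c = confusion_from_predictions(y, preds)
    return RunResult(
        dimension=data.dimension, variation=variation, seed=seed,
        counts=c, accuracy=accuracy(c), f1=f1_score(c),
        predictions=preds, labels=np.asarray(y),
    )


def student_predict_fn(params, s_cfg: StudentConfig):
    def predict(eeg, eog):
        with no_grad():
            preds = []
            for lo in range(0, len(eog), 256):
                out = student_forward(params, eog[lo : lo + 256], s_cfg, rng=None)
                preds.append(out.probabilities.data.argmax(axis=-1))
        return np.concatenate(preds)

    return predict


def teacher_predict_fn(params, t_cfg: TeacherConfig):
    from .teacher import teacher_forward

    def predict(eeg, eog):
        with no_grad():
            preds = []
            for lo in range(0, len(eog), 256):
                out = teacher_forward(params, eeg[lo : lo + 256], eog[lo : lo + 256], t_cfg, rng=None)
                preds.append(out.probabilities.data.argmax(axis=-1))
        return np.concatenate(preds)

    return predict


# ---------------------------------------------------------------------------
# ablation driver
# ---------------------------------------------------------------------------


def run_ablation(
    segments,
    recordings,
    t_cfg: TeacherConfig,
    s_cfg: StudentConfig,
    seeds,
    dimensions=("valence", "arousal"),
    weights: LossWeights = LossWeights(),
    schedule: FeedbackSchedule = FeedbackSchedule(),
    epochs: int = 12,
    teacher_epochs: int = 12,
    batch_size: int = 64,
    lr: float = 1e-3,
    variations=(1, 2, 3),
):
    """Train V1/V2/V3 per (seed, dimension), reusing one pretrained teacher
    per (seed, dimension); returns (per-run DataFrame, summary DataFrame,
    V3-vs-V1 paired t-tests per dimension)."""
    seeds = list(seeds)
    if len(seeds) < 3:
        raise ValidationError("ablation needs at least 3 seeds")
    rows = []
    for seed in seeds:
        split = split_per_subject(recordings, seed=seed)
        for dim in dimensions:
            data = PartitionedData(segments, split, dim)
            teacher_params, _ = pretrain_teacher(
                data.arrays("train", "teacher-pretrain"),
                data.arrays("val", "teacher-val"),
                t_cfg, epochs=teacher_epochs, batch_size=batch_size, lr=lr, seed=seed,
            )
            rows.append(
                evaluate_model(
                    teacher_predict_fn(teacher_params, t_cfg), data.with_fresh_log(),
                    variation="teacher", seed=seed,
                ).to_record()
            )
            for v in variations:
                # fresh audit log per run: test partition read exactly once
                d = data.with_fresh_log()
                res = run_distillation(
                    d, v, t_cfg, s_cfg, weights=weights, schedule=schedule,
                    epochs=epochs, batch_size=batch_size, lr=lr, seed=seed,
                    teacher_params=teacher_params,
                )
                rr = evaluate_model(
                    student_predict_fn(res.student_params, s_cfg), d,
                    variation=v, seed=seed,
                )
                rows.append(rr.to_record())
    table = pd.DataFrame(rows)
    summary = (
        table.groupby(["variation", "dimension"])[["accuracy", "f1"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    ttests = {}
    if set((1, 3)) <= set(variations):
        for dim in dimensions:
            sub = table[table.dimension == dim].pivot(
                index="seed", columns="variation", values="accuracy"
            )
            ttests[dim] = paired_ttest(sub[3].values, sub[1].values)
    return table, summary, ttests


# ---------------------------------------------------------------------------
# leakage demonstration
# ---------------------------------------------------------------------------


class _SegmentLevelData(PartitionedData):
    """Segment-shuffled regime: identical partition sizes, but segments are
    assigned to partitions individually, ignoring trial boundaries."""

    def __init__(self, segments, sizes, dimension, rng):
        self.dimension = dimension
        self.split = None
        self.access_log = []
        perm = rng.permutation(len(segments))
        a, b = sizes[0], sizes[0] + sizes[1]
        groups = {
            "train": [segments[i] for i in perm[:a]],
            "val": [segments[i] for i in perm[a:b]],
            "test": [segments[i] for i in perm[b:]],
        }
        self._parts = {
            part: segments_to_arrays(group, dimension) for part, group in groups.items()
        }


def leakage_experiment(
    segments,
    recordings,
    t_cfg: TeacherConfig,
    seed: int = 0,
    dimension: str = "valence",
    epochs: int = 8,
    batch_size: int = 64,
    lr: float = 1e-3,
):
    """Train identical multimodal models under trial-wise vs segment-shuffled
    splitting; report the accuracy-inflation gap (shuffled minus trial-wise).
    """
    split = split_per_subject(recordings, seed=seed)
    trialwise = PartitionedData(segments, split, dimension)
    sizes = tuple(trialwise.n(p) for p in ("train", "val", "test"))
    shuffled = _SegmentLevelData(
        segments, sizes, dimension, np.random.default_rng(seed + 10_000)
    )
    out = {}
    for regime, data in (("trial_wise", trialwise), ("segment_shuffled", shuffled)):
        # fixed training budget, final-epoch model: checkpoint selection on a
        # leaky validation set would otherwise confound the regime comparison
        params, _ = pretrain_teacher(
            data.arrays("train", "train"), data.arrays("val", "val"),
            t_cfg, epochs=epochs, batch_size=batch_size, lr=lr, seed=seed,
            select="final",
        )
        eeg, eog, y = data.arrays("test", "final-eval")
        _, acc = evaluate_teacher(params, (eeg, eog, y), t_cfg)
        out[regime] = acc
    out["gap"] = out["segment_shuffled"] - out["trial_wise"]
    out["n_segments"] = sum(sizes)
    return out
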
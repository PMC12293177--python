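"""Run configuration: YAML loading, schema validation, pipeline driver.

A :class:`RunConfig` bundles every knob of a reproducible run — data source,
label rule, split ratios, model widths, loss weights, feedback schedule and
training budget. Unknown keys are rejected with the path to the offending
entry; an empty file yields the pure defaults (loss weights 1:1:1, feedback
scale 1, 128 Hz, 4 s windows, 8:1:1 trial split). One global seed fans out
to named sub-streams (cohort, initialization, batch order, feedback
sampling) via numpy SeedSequence spawning.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    LabelSpec,
    ValidationError,
    load_recordings,
    save_recordings,
    segment_trial,
    split_per_subject,
)
from .distill import FeedbackSchedule, LossWeights, PartitionedData, run_distillation
from .evaluation import evaluate_model, leakage_experiment, run_ablation, student_predict_fn
from .models import load_params, save_params
from .student import StudentConfig
from .synthetic import CohortSpec, generate_cohort
from .teacher import TeacherConfig, pretrain_teacher

__all__ = ["RunConfig", "ModelSizes", "TrainingBudget", "load_config", "run_pipeline"]


@dataclasses.dataclass(frozen=True)
class ModelSizes:
    """Widths shared by teacher and student; the compact defaults are the
    package's standard synthetic benchmark scale."""

    d_model: int = 32
    n_heads: int = 4
    d_ff: int = 64
    n_temporal_maps: int = 4
    dropout: float = 0.1
    use_positions: bool = True


@dataclasses.dataclass(frozen=True)
class TrainingBudget:
    epochs: int = 12
    teacher_epochs: int = 12
    batch_size: int = 64
    lr: float = 3e-3


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    ratios: tuple = (8, 1, 1)

    def __post_init__(self):
        if len(self.ratios) != 3 or any(r <= 0 for r in self.ratios):
            raise ValidationError("split.ratios must be three positive numbers")


@dataclasses.dataclass(frozen=True)
class DataSource:
    source: str = "synthetic"          # "synthetic" | "container" | "deap_python"
    path: str | None = None
    cohort: CohortSpec = CohortSpec()

    def __post_init__(self):
        if self.source not in ("synthetic", "container", "deap_python"):
            raise ValidationError(f"unknown data source {self.source!r}")
        if self.source != "synthetic" and not self.path:
            raise ValidationError(f"data source {self.source!r} requires data.path")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    data: DataSource = DataSource()
    label_threshold: float = 5.0
    split: SplitSpec = SplitSpec()
    window_seconds: float = 4.0
    model: ModelSizes = ModelSizes()
    loss: LossWeights = LossWeights()
    feedback: FeedbackSchedule = FeedbackSchedule()
    training: TrainingBudget = TrainingBudget()
    seed: int = 0
    out_dir: str = "runs"

    # -- derived model configs -------------------------------------------
    def teacher_config(self) -> TeacherConfig:
        m, c = self.model, self.data.cohort
        return TeacherConfig(
            n_eeg_channels=c.n_eeg_channels, n_eog_channels=c.n_eog_channels, fs=c.fs,
            d_model=m.d_model, n_heads=m.n_heads, d_ff=m.d_ff,
            n_temporal_maps=m.n_temporal_maps, dropout=m.dropout,
            use_positions=m.use_positions,
        )

    def student_config(self) -> StudentConfig:
        m, c = self.model, self.data.cohort
        return StudentConfig(
            n_eog_channels=c.n_eog_channels, fs=c.fs,
            d_model=m.d_model, n_heads=m.n_heads, d_ff=m.d_ff,
            n_temporal_maps=m.n_temporal_maps, dropout=m.dropout,
            use_positions=m.use_positions, teacher_width=2 * m.d_model,
        )

    def to_dict(self) -> dict:
        def unfold(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: unfold(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        d = unfold(self)
        return d

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


_SECTION_TYPES = {
    "data": DataSource,
    "split": SplitSpec,
    "model": ModelSizes,
    "loss": LossWeights,
    "feedback": FeedbackSchedule,
    "training": TrainingBudget,
}


def _build(cls, mapping, path):
    if mapping is None:
        mapping = {}
    if not isinstance(mapping, dict):
        raise ValidationError(f"config section '{path}' must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in mapping.items():
        if key not in fields:
            raise ValidationError(f"unknown config key '{path}.{key}'")
        if key == "cohort":
            value = _build(CohortSpec, value, f"{path}.cohort")
        elif key == "ratios":
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; missing keys take the defaults."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValidationError("config root must be a mapping")
    if overrides:
        raw = {**raw, **overrides}
    kwargs = {}
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    for key, value in raw.items():
        if key not in top_fields:
            raise ValidationError(f"unknown config key '{key}'")
        if key in _SECTION_TYPES:
            value = _build(_SECTION_TYPES[key], value, key)
        kwargs[key] = value
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


class MissingArtifactError(FileNotFoundError):
    pass


def _cohort_path(run_dir: Path) -> Path:
    return run_dir / "cohort.h5"


def _load_cohort(cfg: RunConfig, run_dir: Path):
    if cfg.data.source == "synthetic":
        p = _cohort_path(run_dir)
        if p.exists():
            return load_recordings(p, "container")
        recs, _ = generate_cohort(dataclasses.replace(cfg.data.cohort, seed=cfg.seed))
        return recs
    return load_recordings(cfg.data.path, cfg.data.source)


def _segments(cfg: RunConfig, recordings):
    specs = {d: LabelSpec(d, cfg.label_threshold) for d in ("valence", "arousal")}
    segs = []
    for rec in recordings:
        segs.extend(segment_trial(rec, cfg.window_seconds, label_specs=specs))
    return segs


def run_pipeline(cfg: RunConfig, command: str, run_dir=None) -> Path:
    """Execute one pipeline stage; artifacts land under the run directory."""
    import time

    if run_dir is None:
        run_dir = Path(cfg.out_dir) / time.strftime("%Y%m%d-%H%M%S")
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.save(run_dir / "resolved_config.yaml")

    if command == "simulate":
        recs, _ = generate_cohort(dataclasses.replace(cfg.data.cohort, seed=cfg.seed))
        save_recordings(recs, _cohort_path(run_dir))
        return run_dir

    recordings = _load_cohort(cfg, run_dir)
    segments = _segments(cfg, recordings)
    split = split_per_subject(recordings, cfg.split.ratios, seed=cfg.seed)
    split.to_json(run_dir / "split.json")
    t_cfg, s_cfg = cfg.teacher_config(), cfg.student_config()
    tb = cfg.training

    if command == "pretrain":
        for dim in ("valence", "arousal"):
            data = PartitionedData(segments, split, dim)
            params, history = pretrain_teacher(
                data.arrays("train", "teacher-pretrain"),
                data.arrays("val", "teacher-val"),
                t_cfg, epochs=tb.teacher_epochs, batch_size=tb.batch_size,
                lr=tb.lr, seed=cfg.seed,
            )
            save_params(params, run_dir / f"teacher_{dim}.npz")
            pd.DataFrame(history).to_csv(run_dir / f"teacher_{dim}_log.csv", index=False)
        return run_dir

    if command == "distill":
        variation = getattr(cfg, "_variation", 3)
        metrics_rows = []
        for dim in ("valence", "arousal"):
            data = PartitionedData(segments, split, dim)
            t_path = run_dir / f"teacher_{dim}.npz"
            teacher_params = load_params(t_path) if t_path.exists() else None
            res = run_distillation(
                data, variation, t_cfg, s_cfg, weights=cfg.loss, schedule=cfg.feedback,
                epochs=tb.epochs, batch_size=tb.batch_size, lr=tb.lr,
                teacher_epochs=tb.teacher_epochs, seed=cfg.seed,
                teacher_params=teacher_params,
            )
            save_params(res.student_params, run_dir / f"student_{dim}_v{variation}.npz")
            pd.DataFrame(res.history).to_csv(
                run_dir / f"student_{dim}_v{variation}_log.csv", index=False
            )
            rr = evaluate_model(
                student_predict_fn(res.student_params, s_cfg), data,
                variation=variation, seed=cfg.seed,
            )
            metrics_rows.append(rr.to_record())
        pd.DataFrame(metrics_rows).to_csv(run_dir / "metrics.csv", index=False)
        return run_dir

    if command == "evaluate":
        rows = []
        for dim in ("valence", "arousal"):
            data = PartitionedData(segments, split, dim)
            found = sorted(run_dir.glob(f"student_{dim}_v*.npz"))
            if not found:
                raise MissingArtifactError(
                    f"no student checkpoint for '{dim}' in {run_dir}; run `emokd distill` first"
                )
            params = load_params(found[-1])
            rr = evaluate_model(student_predict_fn(params, s_cfg), data, seed=cfg.seed)
            rows.append(rr.to_record())
        pd.DataFrame(rows).to_csv(run_dir / "metrics.csv", index=False)
        return run_dir

    if command == "ablate":
        seeds = [cfg.seed + i for i in range(3)]
        table, summary, ttests = run_ablation(
            segments, recordings, t_cfg, s_cfg, seeds,
            weights=cfg.loss, schedule=cfg.feedback,
            epochs=tb.epochs, teacher_epochs=tb.teacher_epochs,
            batch_size=tb.batch_size, lr=tb.lr,
        )
        table.to_csv(run_dir / "ablation.csv", index=False)
        summary.to_csv(run_dir / "ablation_summary.csv")
        (run_dir / "ablation_ttests.json").write_text(json.dumps(ttests))
        return run_dir

    if command == "leakage-demo":
        out = leakage_experiment(
            segments, recordings, t_cfg, seed=cfg.seed,
            epochs=max(tb.teacher_epochs // 2, 4), batch_size=tb.batch_size, lr=tb.lr,
        )
        (run_dir / "leakage.json").write_text(json.dumps(out, indent=1))
        return run_dir

    raise ValidationError(f"unknown pipeline command {command!r}")
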
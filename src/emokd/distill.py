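"""Distillation objective and the two-phase dynamic-feedback training loop.

The student objective blends three terms,

    L_S = l1 * CE(y, student) + l2 * KL(teacher || student) + l3 * MSE(F_S, F_T),

where F_S is the student's aligned fused feature and F_T the teacher's fused
feature. Training alternates between:

* the *teaching phase* — Adam steps on L_S updating only the student; and
* the *feedback phase* — a temporary student copy takes one inner gradient
  step on L_S, and the teacher is updated on *validation* data by descending
  CE(y_V, student(x_V; th_ts)) + lt * CE(y_V, teacher(x_V; th_t)), the first
  term's teacher-dependence flowing through the inner step (exact
  second-order by default; a cheaper first-order mode drops that pathway).

Three ablation variations are supported: V1 is classic logit-only soft-label
distillation (no feature matching, static teacher), V2 adds the feature
term, V3 adds dynamic feedback.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_model import ValidationError, segments_to_arrays
from .nn import ParamDict, Tensor, clip_min, grad, log, no_grad, one_hot, softmax
from .nn.optim import Adam, clone_params, params_fingerprint
from .student import StudentConfig, init_student, student_forward
from .teacher import TeacherConfig, pretrain_teacher, teacher_forward

__all__ = [
    "LossWeights",
    "FeedbackSchedule",
    "DistillState",
    "loss_ce",
    "loss_mse",
    "loss_kl",
    "total_student_loss",
    "teach_phase",
    "feedback_phase",
    "run_distillation",
    "PartitionedData",
    "evaluate_student",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# loss weights and schedule
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class LossWeights:
    """Balance coefficients of the student objective (defaults 1:1:1) plus
    the feedback scaling factor and soft-label temperature."""

    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 1.0
    lambda_t: float = 1.0
    temperature: float = 1.0

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda3, self.lambda_t) < 0:
            raise ValidationError("loss weights must be non-negative")
        if self.lambda1 + self.lambda2 + self.lambda3 <= 0:
            raise ValidationError("at least one loss weight must be positive")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")


@dataclasses.dataclass(frozen=True)
class FeedbackSchedule:
    """Cadence and step sizes of the feedback phase."""

    warmup_epochs: int = 5
    steps_per_epoch: int = 1
    alpha: float = 1e-3       # inner (temporary-student) plain-GD step
    outer_lr: float = 1e-3    # teacher Adam step
    mode: str = "exact"       # "exact" second-order | "first_order"
    #: guarded descent: re-evaluate the outer objective after the teacher
    #: update and revert updates that worsened it, so feedback cannot
    #: degrade the guidance it is meant to improve
    guarded: bool = True

    def __post_init__(self):
        if self.alpha < 0:
            raise ValidationError("inner learning rate alpha must be non-negative")
        if self.mode not in ("exact", "first_order"):
            raise ValidationError(f"unknown feedback mode {self.mode!r}")


@dataclasses.dataclass
class DistillState:
    theta_t: ParamDict
    theta_s: ParamDict
    theta_ts: ParamDict | None = None
    cycle: int = 0
    phase: str = "teach"
    history: list = dataclasses.field(default_factory=list)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def _as_prob_tensor(p, name: str) -> Tensor:
    t = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=np.float64))
    sums = t.data.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-3):
        raise ValidationError(f"{name} is not normalized (row sums deviate by > 1e-3)")
    return t


def loss_ce(y, y_hat) -> Tensor:
    """Cross-entropy -sum_k y_k log y_hat_k, batch-averaged.

    ``y`` is one-hot (or integer labels); ``y_hat`` a simplex vector whose
    components are clipped to [1e-12, 1] before the log.
    """
    y_hat = _as_prob_tensor(y_hat, "y_hat")
    y = np.asarray(y.data if isinstance(y, Tensor) else y, dtype=np.float64)
    if y.ndim <= 1 and y_hat.data.ndim > y.ndim:
        y = one_hot(np.atleast_1d(y), y_hat.shape[-1])
        if y_hat.data.ndim == 1:
            y = y[0]
    ce = -(Tensor(y) * log(clip_min(y_hat, _EPS))).sum()
    batch = 1 if y_hat.data.ndim == 1 else y_hat.shape[0]
    return ce * (1.0 / batch)


def loss_mse(f_s, f_t) -> Tensor:
    """Mean squared error over feature components, batch-averaged."""
    f_s = f_s if isinstance(f_s, Tensor) else Tensor(np.asarray(f_s, dtype=np.float64))
    f_t = f_t if isinstance(f_t, Tensor) else Tensor(np.asarray(f_t, dtype=np.float64))
    if f_s.shape != f_t.shape:
        raise ValidationError(f"feature widths differ: {f_s.shape} vs {f_t.shape}")
    d = f_s - f_t
    n = f_s.shape[-1]
    batch = 1 if f_s.data.ndim == 1 else f_s.shape[0]
    return (d * d).sum() * (1.0 / (n * batch))


def loss_kl(teacher_probs, student_probs, temperature: float = 1.0,
            teacher_logits=None, student_logits=None) -> Tensor:
    """KL(teacher || student), batch-averaged; always non-negative.

    With ``temperature != 1`` both distributions are re-softened from their
    logits at that temperature and the result is scaled by T^2.
    """
    if temperature != 1.0:
        if teacher_logits is None or student_logits is None:
            raise ValidationError("temperature != 1 requires both logits")
        teacher_probs = softmax(teacher_logits * (1.0 / temperature), axis=-1)
        student_probs = softmax(student_logits * (1.0 / temperature), axis=-1)
    p_t = _as_prob_tensor(teacher_probs, "teacher_probs")
    p_s = _as_prob_tensor(student_probs, "student_probs")
    p_t_c = clip_min(p_t, _EPS)
    p_s_c = clip_min(p_s, _EPS)
    kl = (p_t * (log(p_t_c) - log(p_s_c))).sum()
    batch = 1 if p_t.data.ndim == 1 else p_t.shape[0]
    scale = temperature**2 if temperature != 1.0 else 1.0
    return kl * (scale / batch)


def total_student_loss(
    eeg, eog, y,
    theta_s: ParamDict, theta_t: ParamDict,
    weights: LossWeights, t_cfg: TeacherConfig, s_cfg: StudentConfig,
    rng: np.random.Generator | None = None,
    teacher_in_graph: bool = False,
    align_mode: str = "fused",
    hard_targets: str = "ground_truth",
):
    """The three-term objective L_S on one batch.

    Returns (loss Tensor, per-term floats, student output). The teacher runs
    in evaluation mode; its outputs are detached from the graph unless
    ``teacher_in_graph`` (needed by the feedback inner step).
    """
    if teacher_in_graph:
        t_out = teacher_forward(theta_t, eeg, eog, t_cfg, rng=None)
    else:
        with no_grad():
            t_out = teacher_forward(theta_t, eeg, eog, t_cfg, rng=None)
    s_out = student_forward(theta_s, eog, s_cfg, rng=rng)

    y = np.asarray(y)
    if hard_targets == "teacher":
        y_ce = t_out.probabilities.data.argmax(axis=-1)
    elif hard_targets == "ground_truth":
        y_ce = y
    else:
        raise ValidationError(f"unknown hard_targets {hard_targets!r}")

    ce = loss_ce(y_ce, s_out.probabilities)
    kl = loss_kl(
        t_out.probabilities, s_out.probabilities, weights.temperature,
        teacher_logits=t_out.logits, student_logits=s_out.logits,
    )
    if align_mode == "fused":
        f_t, f_s = t_out.fused, s_out.aligned
    elif align_mode == "taps":
        f_t = sum(t_out.taps.values()) * 0.25
        f_s = sum(s_out.taps.values()) * (1.0 / 3.0)
    else:
        raise ValidationError(f"unknown align_mode {align_mode!r}")
    mse = loss_mse(f_s, f_t)

    total = weights.lambda1 * ce + weights.lambda2 * kl + weights.lambda3 * mse
    if not np.isfinite(total.item()):
        raise FloatingPointError("non-finite student loss on current batch")
    parts = {"ce": ce.item(), "kl": kl.item(), "mse": mse.item(), "total": total.item()}
    return total, parts, s_out


# ---------------------------------------------------------------------------
# access-audited partitioned data
# ---------------------------------------------------------------------------


class PartitionedData:
    """Segments grouped by trial-split partition, with an access audit log.

    Every array handed out is recorded as (partition, context) so the
    protocol-integrity tests can assert the test partition is read exactly
    once, at final evaluation.
    """

    def __init__(self, segments, split, dimension: str):
        self.dimension = dimension
        self.split = split
        self.access_log: list[tuple[str, str]] = []
        self._parts = {}
        for part in ("train", "val", "test"):
            subset = [s for s in segments if split.partition_of(s.trial_key) == part]
            if subset:
                self._parts[part] = segments_to_arrays(subset, dimension)
            else:
                self._parts[part] = (np.empty((0,)),) * 3 + ([],)

    def n(self, part: str) -> int:
        return len(self._parts[part][2])

    def with_fresh_log(self) -> "PartitionedData":
        """A view over the same arrays with an empty access log."""
        clone = object.__new__(PartitionedData)
        clone.dimension = self.dimension
        clone.split = self.split
        clone._parts = self._parts
        clone.access_log = []
        return clone

    def arrays(self, part: str, context: str):
        self.access_log.append((part, context))
        eeg, eog, y, _ = self._parts[part]
        return eeg, eog, y

    def sample_batch(self, part: str, rng: np.random.Generator, batch_size: int, context: str):
        eeg, eog, y = self.arrays(part, context)
        idx = rng.choice(len(y), size=min(batch_size, len(y)), replace=False)
        return eeg[idx], eog[idx], y[idx]


# ---------------------------------------------------------------------------
# the two phases
# ---------------------------------------------------------------------------


def teach_phase(
    state: DistillState, batches, weights: LossWeights,
    t_cfg: TeacherConfig, s_cfg: StudentConfig, opt_s: Adam,
    rng: np.random.Generator | None = None,
    align_mode: str = "fused", hard_targets: str = "ground_truth",
) -> dict:
    """Adam steps on L_S updating only the student; the teacher is frozen."""
    state.phase = "teach"
    t_hash = params_fingerprint(state.theta_t)
    agg = {"ce": 0.0, "kl": 0.0, "mse": 0.0, "total": 0.0}
    n = 0
    for eeg, eog, y in batches:
        loss, parts, _ = total_student_loss(
            eeg, eog, y, state.theta_s, state.theta_t, weights, t_cfg, s_cfg,
            rng=rng, align_mode=align_mode, hard_targets=hard_targets,
        )
        names = sorted(state.theta_s)
        grads = grad(loss, [state.theta_s[k] for k in names])
        opt_s.step(state.theta_s, dict(zip(names, grads)))
        for k in agg:
            agg[k] += parts[k]
        n += 1
    assert params_fingerprint(state.theta_t) == t_hash, "teach phase mutated the teacher"
    return {k: v / max(n, 1) for k, v in agg.items()}


def feedback_phase(
    state: DistillState, train_batch, val_batch,
    weights: LossWeights, schedule: FeedbackSchedule,
    t_cfg: TeacherConfig, s_cfg: StudentConfig, opt_t: Adam,
    align_mode: str = "fused", hard_targets: str = "ground_truth",
) -> dict:
    """One feedback cycle: inner step on a training batch, outer teacher
    update on a validation batch. The student proper is never touched."""
    state.phase = "feedback"
    s_hash = params_fingerprint(state.theta_s)
    eeg_b, eog_b, y_b = train_batch
    eeg_v, eog_v, y_v = val_batch
    create_graph = schedule.mode == "exact"

    # inner step: temporary student th_ts = th_s - alpha dL_S/dth_s
    inner_loss, _, _ = total_student_loss(
        eeg_b, eog_b, y_b, state.theta_s, state.theta_t, weights, t_cfg, s_cfg,
        rng=None, teacher_in_graph=True, align_mode=align_mode, hard_targets=hard_targets,
    )
    names_s = sorted(state.theta_s)
    g_inner = grad(inner_loss, [state.theta_s[k] for k in names_s], create_graph=create_graph)
    theta_ts = {
        k: state.theta_s[k].detach() + (-schedule.alpha) * g
        for k, g in zip(names_s, g_inner)
    }

    # outer step on validation data
    s_out_v = student_forward(theta_ts, eog_v, s_cfg, rng=None)
    t_out_v = teacher_forward(state.theta_t, eeg_v, eog_v, t_cfg, rng=None)
    outer = loss_ce(y_v, s_out_v.probabilities) + weights.lambda_t * loss_ce(y_v, t_out_v.probabilities)
    names_t = sorted(state.theta_t)
    snap = (clone_params(state.theta_t), opt_t.snapshot()) if schedule.guarded else None
    g_outer = grad(outer, [state.theta_t[k] for k in names_t])
    opt_t.step(state.theta_t, dict(zip(names_t, g_outer)))

    accepted = True
    if schedule.guarded:
        # guarded descent: recompute the outer objective under the updated
        # teacher (fresh inner step included) and revert a harmful update
        new_outer = _outer_objective_value(
            state, train_batch, val_batch, weights, schedule, t_cfg, s_cfg,
            align_mode=align_mode, hard_targets=hard_targets,
        )
        if new_outer > outer.item():
            old_params, old_opt = snap
            for k in names_t:
                state.theta_t[k].data = old_params[k].data
            opt_t.restore(old_opt)
            accepted = False

    state.theta_ts = {k: v.detach() for k, v in theta_ts.items()}
    state.cycle += 1
    assert params_fingerprint(state.theta_s) == s_hash, "feedback phase mutated the student"
    return {"inner_loss": inner_loss.item(), "outer_loss": outer.item(),
            "feedback_accepted": float(accepted)}


def _outer_objective_value(
    state: DistillState, train_batch, val_batch,
    weights: LossWeights, schedule: FeedbackSchedule,
    t_cfg: TeacherConfig, s_cfg: StudentConfig,
    align_mode: str = "fused", hard_targets: str = "ground_truth",
) -> float:
    eeg_b, eog_b, y_b = train_batch
    eeg_v, eog_v, y_v = val_batch
    inner, _, _ = total_student_loss(
        eeg_b, eog_b, y_b, state.theta_s, state.theta_t, weights, t_cfg, s_cfg,
        rng=None, align_mode=align_mode, hard_targets=hard_targets,
    )
    names_s = sorted(state.theta_s)
    g = grad(inner, [state.theta_s[k] for k in names_s])
    theta_ts = {k: Tensor(state.theta_s[k].data - schedule.alpha * gi.data)
                for k, gi in zip(names_s, g)}
    with no_grad():
        s_out = student_forward(theta_ts, eog_v, s_cfg, rng=None)
        t_out = teacher_forward(state.theta_t, eeg_v, eog_v, t_cfg, rng=None)
    return (loss_ce(y_v, s_out.probabilities)
            + weights.lambda_t * loss_ce(y_v, t_out.probabilities)).item()


def feedback_outer_gradient(
    state: DistillState, train_batch, val_batch,
    weights: LossWeights, schedule: FeedbackSchedule,
    t_cfg: TeacherConfig, s_cfg: StudentConfig,
    align_mode: str = "fused",
) -> dict[str, np.ndarray]:
    """The outer gradient w.r.t. the teacher, without applying any update.

    Exposed so its correctness can be audited against finite differences
    through the full inner-step computation.
    """
    eeg_b, eog_b, y_b = train_batch
    eeg_v, eog_v, y_v = val_batch
    inner_loss, _, _ = total_student_loss(
        eeg_b, eog_b, y_b, state.theta_s, state.theta_t, weights, t_cfg, s_cfg,
        rng=None, teacher_in_graph=True, align_mode=align_mode,
    )
    names_s = sorted(state.theta_s)
    g_inner = grad(inner_loss, [state.theta_s[k] for k in names_s],
                   create_graph=schedule.mode == "exact")
    theta_ts = {
        k: state.theta_s[k].detach() + (-schedule.alpha) * g
        for k, g in zip(names_s, g_inner)
    }
    s_out_v = student_forward(theta_ts, eog_v, s_cfg, rng=None)
    t_out_v = teacher_forward(state.theta_t, eeg_v, eog_v, t_cfg, rng=None)
    outer = loss_ce(y_v, s_out_v.probabilities) + weights.lambda_t * loss_ce(y_v, t_out_v.probabilities)
    names_t = sorted(state.theta_t)
    g_outer = grad(outer, [state.theta_t[k] for k in names_t])
    return {k: g.data for k, g in zip(names_t, g_outer)}


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class DistillResult:
    student_params: ParamDict
    teacher_params: ParamDict
    state: DistillState
    history: list
    best_val_acc: float
    variation: int
    seed: int


def evaluate_student(params: ParamDict, data, cfg: StudentConfig, batch_size: int = 256):
    """Evaluation-mode CE and accuracy of the student on (eog, y)."""
    eog, y = data
    total_loss, correct = 0.0, 0
    with no_grad():
        for lo in range(0, len(y), batch_size):
            sl = slice(lo, lo + batch_size)
            out = student_forward(params, eog[sl], cfg, rng=None)
            total_loss += loss_ce(y[sl], out.probabilities).item() * len(y[sl])
            correct += int((out.probabilities.data.argmax(axis=-1) == y[sl]).sum())
    return total_loss / len(y), correct / len(y)


def run_distillation(
    data: PartitionedData,
    variation: int,
    t_cfg: TeacherConfig,
    s_cfg: StudentConfig,
    weights: LossWeights = LossWeights(),
    schedule: FeedbackSchedule = FeedbackSchedule(),
    epochs: int = 12,
    batch_size: int = 64,
    lr: float = 1e-3,
    teacher_epochs: int = 12,
    seed: int = 0,
    teacher_params: ParamDict | None = None,
    align_mode: str = "fused",
    hard_targets: str = "ground_truth",
) -> DistillResult:
    """Train a student under one ablation variation.

    V1 — logit-only static distillation (feature term off, teacher frozen);
    V2 — full three-term objective, teacher frozen;
    V3 — full objective with dynamic-feedback teacher updates.
    The best-validation student checkpoint is returned.
    """
    if variation not in (1, 2, 3):
        raise ValidationError(f"variation must be 1, 2 or 3, got {variation}")
    from .models import batch_indices

    ss = np.random.SeedSequence(seed)
    init_rng, drop_rng, batch_rng, fb_rng, t_seed = ss.spawn(5)
    if teacher_params is None:
        teacher_params, _ = pretrain_teacher(
            data.arrays("train", "teacher-pretrain"),
            data.arrays("val", "teacher-val"),
            t_cfg, epochs=teacher_epochs, batch_size=batch_size, lr=lr,
            seed=int(t_seed.generate_state(1)[0] % (2**31)),
        )
    theta_t = clone_params(teacher_params)
    theta_s = init_student(s_cfg, np.random.default_rng(init_rng))
    state = DistillState(theta_t=theta_t, theta_s=theta_s)

    w = dataclasses.replace(weights, lambda3=0.0) if variation == 1 else weights
    opt_s = Adam(lr=lr)
    opt_t = Adam(lr=schedule.outer_lr)
    drop = np.random.default_rng(drop_rng)
    brng = np.random.default_rng(batch_rng)
    frng = np.random.default_rng(fb_rng)

    teacher_hash_before = params_fingerprint(theta_t)
    best = (clone_params(theta_s), -np.inf)
    for epoch in range(epochs):
        eeg_tr, eog_tr, y_tr = data.arrays("train", "teach-phase")
        batches = (
            (eeg_tr[idx], eog_tr[idx], y_tr[idx])
            for idx in batch_indices(brng, len(y_tr), batch_size)
        )
        train_parts = teach_phase(
            state, batches, w, t_cfg, s_cfg, opt_s, rng=drop,
            align_mode=align_mode, hard_targets=hard_targets,
        )
        eog_va, y_va = data.arrays("val", "student-val")[1:]
        val_loss, val_acc = evaluate_student(state.theta_s, (eog_va, y_va), s_cfg)
        record = {"epoch": epoch, "val_loss": val_loss, "val_acc": val_acc, **{
            f"train_{k}": v for k, v in train_parts.items()}}
        if variation == 3 and epoch >= schedule.warmup_epochs:
            for _ in range(schedule.steps_per_epoch):
                fb = feedback_phase(
                    state,
                    data.sample_batch("train", frng, batch_size, "feedback-inner"),
                    data.sample_batch("val", frng, batch_size, "feedback-outer"),
                    w, schedule, t_cfg, s_cfg, opt_t,
                    align_mode=align_mode, hard_targets=hard_targets,
                )
                record.update(fb)
        state.history.append(record)
        if val_acc > best[1]:
            best = (clone_params(state.theta_s), val_acc)
    if variation in (1, 2):
        assert params_fingerprint(theta_t) == teacher_hash_before, \
            "static-teacher contract violated"
    return DistillResult(
        student_params=best[0],
        teacher_params=theta_t,
        state=state,
        history=state.history,
        best_val_acc=best[1],
        variation=variation,
        seed=seed,
    )
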
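"""Trial-structured physiological recordings and the leakage-safe protocol.

The unit of acquisition is a *trial*: one presentation of an affective
stimulus, recorded simultaneously as multichannel EEG and EOG, rated
afterwards on continuous 1-9 valence/arousal scales. The unit of learning
is a *segment*: a fixed-length (default 4 s) non-overlapping window cut
from a trial. Because consecutive segments of one trial are strongly
correlated, the train/validation/test partition is made at the trial
level — never at the segment level — so that no trial contributes segments
to more than one partition.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pickle
from pathlib import Path

import numpy as np
from scipy import signal as _sig

logger = logging.getLogger(__name__)

DIMENSIONS = ("valence", "arousal")

#: DEAP peripheral-block channel offsets for the two dedicated EOG leads
#: (horizontal EOG, vertical EOG) immediately after the 32 EEG channels.
DEAP_N_EEG = 32
DEAP_EOG_CHANNELS = (32, 33)
DEAP_BASELINE_SECONDS = 3.0


class ValidationError(ValueError):
    """Raised when domain invariants are violated."""


@dataclasses.dataclass
class Recording:
    """One trial's simultaneous EEG + EOG signals with its ratings.

    ``eeg`` and ``eog`` are [channels x samples] arrays on a shared clock;
    ``baseline_samples`` counts leading pre-stimulus samples.
    """

    subject_id: str
    trial_id: str
    eeg: np.ndarray
    eog: np.ndarray
    fs: float
    ratings: dict[str, float]
    baseline_samples: int = 0

    def __post_init__(self):
        self.eeg = np.asarray(self.eeg, dtype=np.float64)
        self.eog = np.asarray(self.eog, dtype=np.float64)
        if self.eeg.ndim != 2 or self.eog.ndim != 2:
            raise ValidationError("eeg and eog must be 2-D [channels x samples]")
        if self.eeg.shape[1] != self.eog.shape[1]:
            raise ValidationError(
                f"eeg and eog sample counts differ: {self.eeg.shape[1]} vs {self.eog.shape[1]}"
            )
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        for dim, r in self.ratings.items():
            if not (1.0 <= r <= 9.0):
                raise ValidationError(f"rating {dim}={r} outside [1, 9]")
        if self.baseline_samples >= self.eeg.shape[1]:
            raise ValidationError("baseline_samples must be smaller than the recording")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.trial_id)


@dataclasses.dataclass
class Segment:
    """A fixed-length labeled window of one trial — the training unit."""

    eeg_block: np.ndarray
    eog_block: np.ndarray
    labels: dict[str, int]
    provenance: tuple[str, str, int]  # (subject_id, trial_id, segment_index)

    @property
    def trial_key(self) -> tuple[str, str]:
        return self.provenance[:2]


@dataclasses.dataclass(frozen=True)
class LabelSpec:
    """Binarization rule for a 1-9 rating: class 1 iff rating > threshold."""

    dimension: str = "valence"
    threshold: float = 5.0

    def __post_init__(self):
        if self.dimension not in DIMENSIONS:
            raise ValidationError(f"unknown dimension {self.dimension!r}")
        if not (1.0 < self.threshold < 9.0):
            raise ValidationError("threshold must lie strictly inside (1, 9)")


@dataclasses.dataclass(frozen=True)
class TrialSplit:
    """Disjoint train/val/test partition of (subject_id, trial_id) keys."""

    train_trials: frozenset
    val_trials: frozenset
    test_trials: frozenset
    seed: int | None = None

    def __post_init__(self):
        sets = (self.train_trials, self.val_trials, self.test_trials)
        total = sum(len(s) for s in sets)
        if len(self.train_trials | self.val_trials | self.test_trials) != total:
            raise ValidationError("split partitions overlap")

    @property
    def all_trials(self) -> frozenset:
        return self.train_trials | self.val_trials | self.test_trials

    def partition_of(self, key) -> str:
        if key in self.train_trials:
            return "train"
        if key in self.val_trials:
            return "val"
        if key in self.test_trials:
            return "test"
        raise KeyError(key)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "train": sorted(map(list, self.train_trials)),
            "val": sorted(map(list, self.val_trials)),
            "test": sorted(map(list, self.test_trials)),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "TrialSplit":
        payload = json.loads(Path(path).read_text())
        return cls(
            frozenset(map(tuple, payload["train"])),
            frozenset(map(tuple, payload["val"])),
            frozenset(map(tuple, payload["test"])),
            seed=payload.get("seed"),
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def binarize_rating(rating: float, spec: LabelSpec) -> int:
    """Map a 1-9 rating to {0, 1}: 1 iff rating is strictly above threshold."""
    if not (1.0 <= rating <= 9.0):
        raise ValidationError(f"rating {rating} outside [1, 9]")
    return int(rating > spec.threshold)


def _largest_remainder(n: int, ratios: tuple[float, ...]) -> list[int]:
    total = float(sum(ratios))
    quotas = [n * r / total for r in ratios]
    base = [int(np.floor(q)) for q in quotas]
    short = n - sum(base)
    order = np.argsort([base[i] - quotas[i] for i in range(len(ratios))], kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base


def split_by_trial(trials, ratios: tuple[float, float, float] = (8, 1, 1), seed: int = 0) -> TrialSplit:
    """Partition trial keys into train/val/test by largest-remainder quotas.

    Deterministic given ``seed``; trials are shuffled once, then assigned in
    blocks, so no trial ever lands in two partitions.
    """
    trials = sorted(set(trials))
    if any(r <= 0 for r in ratios):
        raise ValidationError("ratios must be positive")
    if len(trials) < len(ratios):
        raise ValidationError(f"need at least {len(ratios)} trials, got {len(trials)}")
    sizes = _largest_remainder(len(trials), tuple(ratios))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(trials))
    shuffled = [trials[i] for i in perm]
    a, b = sizes[0], sizes[0] + sizes[1]
    return TrialSplit(
        frozenset(shuffled[:a]),
        frozenset(shuffled[a:b]),
        frozenset(shuffled[b:]),
        seed=seed,
    )


def split_per_subject(recordings, ratios=(8, 1, 1), seed: int = 0) -> TrialSplit:
    """Subject-dependent protocol: apply the 8:1:1 trial split within each
    subject's own trials, then pool the partitions."""
    by_subject: dict[str, list] = {}
    for rec in recordings:
        by_subject.setdefault(rec.subject_id, []).append(rec.key)
    train, val, test = set(), set(), set()
    for i, subj in enumerate(sorted(by_subject)):
        sub = split_by_trial(by_subject[subj], ratios, seed=seed + i)
        train |= sub.train_trials
        val |= sub.val_trials
        test |= sub.test_trials
    return TrialSplit(frozenset(train), frozenset(val), frozenset(test), seed=seed)


def segment_trial(
    rec: Recording,
    window_seconds: float = 4.0,
    drop_baseline: bool = True,
    label_specs: dict[str, LabelSpec] | None = None,
) -> list[Segment]:
    """Cut a recording into consecutive non-overlapping labeled windows.

    The leading baseline is discarded first (when ``drop_baseline``); a
    trailing remainder shorter than one window is dropped.
    """
    window = window_seconds * rec.fs
    if abs(window - round(window)) > 1e-9:
        raise ValidationError(f"window_seconds x fs = {window} is not integral")
    window = int(round(window))
    start = rec.baseline_samples if drop_baseline else 0
    usable = rec.n_samples - start
    n_windows = usable // window
    if n_windows == 0:
        logger.warning(
            "trial %s/%s: usable signal (%d samples) shorter than one %d-sample window",
            rec.subject_id, rec.trial_id, usable, window,
        )
        return []
    if label_specs is None:
        label_specs = {d: LabelSpec(d) for d in DIMENSIONS if d in rec.ratings}
    labels = {d: binarize_rating(rec.ratings[d], s) for d, s in label_specs.items()}
    out = []
    for i in range(int(n_windows)):
        lo = start + i * window
        out.append(
            Segment(
                eeg_block=rec.eeg[:, lo : lo + window],
                eog_block=rec.eog[:, lo : lo + window],
                labels=dict(labels),
                provenance=(rec.subject_id, rec.trial_id, i),
            )
        )
    return out


def resample_signal(
    x: np.ndarray, fs_in: float, fs_out: float = 128.0, allow_upsample: bool = False
) -> np.ndarray:
    """Polyphase resampling along the time axis of a [channels x samples] array."""
    if fs_out <= 0 or fs_in <= 0:
        raise ValidationError("sampling rates must be positive")
    if fs_in < fs_out and not allow_upsample:
        raise ValidationError(
            f"refusing to upsample {fs_in} Hz -> {fs_out} Hz (pass allow_upsample=True)"
        )
    x = np.asarray(x, dtype=np.float64)
    if fs_in == fs_out:
        return x.copy()
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    y = _sig.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    target = int(round(x.shape[-1] * fs_out / fs_in))
    if y.shape[-1] > target:
        y = y[..., :target]
    elif y.shape[-1] < target:
        pad = np.zeros(x.shape[:-1] + (target - y.shape[-1],))
        y = np.concatenate([y, pad], axis=-1)
    return y


# ---------------------------------------------------------------------------
# I/O: native HDF5 container and DEAP preprocessed-python layout
# ---------------------------------------------------------------------------


def save_recordings(recordings, path) -> None:
    """Write the native container: /subjects/<id>/trials/<id>/{...}."""
    import h5py

    with h5py.File(path, "w") as f:
        for rec in recordings:
            g = f.require_group(f"subjects/{rec.subject_id}/trials/{rec.trial_id}")
            g.create_dataset("eeg", data=rec.eeg)
            g.create_dataset("eog", data=rec.eog)
            g.attrs["fs"] = rec.fs
            g.attrs["baseline_samples"] = rec.baseline_samples
            for dim, r in rec.ratings.items():
                g.attrs[f"rating_{dim}"] = r


def _load_container(path) -> list[Recording]:
    import h5py

    out = []
    with h5py.File(path, "r") as f:
        if "subjects" not in f:
            raise ValidationError(f"{path}: missing top-level 'subjects' group")
        for subj in sorted(f["subjects"]):
            for trial in sorted(f[f"subjects/{subj}/trials"]):
                g = f[f"subjects/{subj}/trials/{trial}"]
                for field in ("eeg", "eog"):
                    if field not in g:
                        raise ValidationError(f"{path}: trial {subj}/{trial} missing '{field}'")
                ratings = {
                    k[len("rating_") :]: float(v) for k, v in g.attrs.items() if k.startswith("rating_")
                }
                out.append(
                    Recording(
                        subject_id=subj,
                        trial_id=trial,
                        eeg=g["eeg"][()],
                        eog=g["eog"][()],
                        fs=float(g.attrs["fs"]),
                        ratings=ratings,
                        baseline_samples=int(g.attrs["baseline_samples"]),
                    )
                )
    return out


def _load_deap_python(path) -> list[Recording]:
    """One DEAP preprocessed-python subject file: pickled dict with 'data'
    [40 trials x 40 channels x 8064 samples] and 'labels' [40 x 4] ratings
    (valence, arousal, dominance, liking)."""
    path = Path(path)
    with open(path, "rb") as f:
        payload = pickle.load(f, encoding="latin1")
    for field in ("data", "labels"):
        if field not in payload:
            raise ValidationError(f"{path}: DEAP file missing '{field}' entry")
    data = np.asarray(payload["data"], dtype=np.float64)
    ratings = np.asarray(payload["labels"], dtype=np.float64)
    if data.ndim != 3:
        raise ValidationError(f"{path}: 'data' must be trials x channels x samples")
    fs = 128.0
    baseline = int(round(DEAP_BASELINE_SECONDS * fs))
    subject = path.stem
    out = []
    for t in range(data.shape[0]):
        out.append(
            Recording(
                subject_id=subject,
                trial_id=f"t{t:02d}",
                eeg=data[t, :DEAP_N_EEG, :],
                eog=data[t, list(DEAP_EOG_CHANNELS), :],
                fs=fs,
                ratings={"valence": float(ratings[t, 0]), "arousal": float(ratings[t, 1])},
                baseline_samples=baseline,
            )
        )
    return out


def load_recordings(path, format: str = "container") -> list[Recording]:
    if format == "container":
        return _load_container(path)
    if format == "deap_python":
        return _load_deap_python(path)
    raise ValidationError(f"unknown format {format!r}; expected 'container' or 'deap_python'")


# ---------------------------------------------------------------------------
# segment assembly for model training
# ---------------------------------------------------------------------------


def segments_to_arrays(segments, dimension: str):
    """Stack segments into (eeg [N,C,T], eog [N,C,T], y [N], keys) arrays."""
    if not segments:
        raise ValidationError("no segments to assemble")
    eeg = np.stack([s.eeg_block for s in segments])
    eog = np.stack([s.eog_block for s in segments])
    y = np.array([s.labels[dimension] for s in segments], dtype=np.int64)
    keys = [s.trial_key for s in segments]
    return eeg, eog, y, keys
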
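import numpy as np
import pytest

from emokd.data_model import segment_trial, split_per_subject
from emokd.distill import PartitionedData
from emokd.student import StudentConfig
from emokd.synthetic import CohortSpec, generate_cohort
from emokd.teacher import TeacherConfig

# compact model widths used throughout the unit tests
SMALL_TEACHER = TeacherConfig(d_model=16, n_heads=2, d_ff=32, n_temporal_maps=2)
SMALL_STUDENT = StudentConfig(d_model=16, n_heads=2, d_ff=32, n_temporal_maps=2, teacher_width=32)

# width-8 toy: 3 EEG channels, 16 Hz, 4 s windows -> 8-step sequences
TOY_TEACHER = TeacherConfig(
    n_eeg_channels=3, n_eog_channels=2, fs=16.0,
    d_model=8, n_heads=2, d_ff=8, n_temporal_maps=2, dropout=0.0,
)
TOY_STUDENT = StudentConfig(
    n_eog_channels=2, fs=16.0,
    d_model=8, n_heads=2, d_ff=8, n_temporal_maps=2, dropout=0.0, teacher_width=16,
)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortSpec(n_subjects=4, n_trials_per_subject=10, seed=1))


@pytest.fixture(scope="session")
def small_segments(small_cohort):
    recs, _ = small_cohort
    segs = []
    for r in recs:
        segs.extend(segment_trial(r))
    return segs


@pytest.fixture(scope="session")
def small_split(small_cohort):
    recs, _ = small_cohort
    return split_per_subject(recs, seed=0)


@pytest.fixture(scope="session")
def small_data(small_segments, small_split):
    return PartitionedData(small_segments, small_split, "valence")


def toy_batch(rng, n=6, t_cfg=TOY_TEACHER):
    """Random (eeg, eog, y) batch shaped for the width-8 toy models."""
    samples = int(4 * t_cfg.fs)
    eeg = rng.standard_normal((n, t_cfg.n_eeg_channels, samples))
    eog = rng.standard_normal((n, t_cfg.n_eog_channels, samples))
    y = rng.integers(0, 2, size=n)
    return eeg, eog, y


def fd_grad_entries(f, params, entries, eps=1e-6):
    """Central finite differences of scalar f(params) at selected entries.

    ``entries`` is a list of (key, flat_index); returns matching FD values.
    """

    def val(v):
        return float(v.item()) if hasattr(v, "item") else float(v)

    out = []
    for key, idx in entries:
        flat = params[key].data.reshape(-1)
        old = flat[idx]
        flat[idx] = old + eps
        fp = val(f(params))
        flat[idx] = old - eps
        fm = val(f(params))
        flat[idx] = old
        out.append((fp - fm) / (2 * eps))
    return np.array(out)


def pick_entries(rng, params, n):
    keys = sorted(params)
    out = []
    for _ in range(n):
        k = keys[rng.integers(len(keys))]
        out.append((k, int(rng.integers(params[k].data.size))))
    return out
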
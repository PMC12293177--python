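"""Synthetic trial-structured EEG + EOG cohorts with known ground truth.

The generator emulates the structure of an affective-rating experiment:
subjects undergo repeated trials, each yielding simultaneous 32-channel EEG
and 2-channel EOG at 128 Hz plus 1-9 valence/arousal self-ratings. Class
information is planted where each modality physiologically carries it:

* EEG — oscillatory band power: alpha (8-13 Hz) amplitude shifts with the
  valence class, beta (14-30 Hz) amplitude with the arousal class, both
  scaled by ``eeg_snr``.
* EOG — ocular events: blink rate shifts with the valence class and slow
  drift power with the arousal class, both scaled by ``eog_snr``.

A smooth order-2 autoregressive latent time course z(t), mixed into both
modalities through per-trial random spatial maps with strength
``shared_latent_weight``, provides (a) the cross-modal common component a
multimodal model can exploit, (b) trial-persistent structure that makes
segment-level splitting leak, and (c) the pathway through which EEG-borne
class evidence reaches EOG: z(t) carries narrow-band components — theta
(6 Hz) for valence, delta (3 Hz) for arousal — whose amplitudes scale with
``sqrt(eeg_snr * class)``, so the strength of the cross-modal class leak is
jointly controlled by ``eeg_snr`` and ``shared_latent_weight`` (either at
zero removes it).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as _sig

from .data_model import LabelSpec, Recording, ValidationError, binarize_rating

__all__ = ["CohortSpec", "GroundTruth", "generate_cohort", "inject_blinks", "blink_template"]

#: modality base amplitudes (arbitrary microvolt-scale units)
_ALPHA_AMP = 1.0
_BETA_AMP = 0.7
_DRIFT_AMP = 2.0
_BLINK_AMP = 8.0
_BLINK_BASE_RATE = 0.25  # Hz
_SHARED_AMP = 1.5
_CLASS_LATENT_SCALE = 0.5


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Generator parameters; defaults are the package's standard benchmark
    conditions (compact cohort, strong EEG class signal, weak EOG one)."""

    n_subjects: int = 20
    n_trials_per_subject: int = 20
    trial_seconds: float = 19.0
    fs: float = 128.0
    n_eeg_channels: int = 32
    n_eog_channels: int = 2
    baseline_seconds: float = 3.0
    class_balance: float = 0.5
    eeg_snr: float = 2.0
    eog_snr: float = 0.5
    shared_latent_weight: float = 0.7
    noise_sd: float = 1.0
    #: draw every stochastic process independently per analysis window
    #: (boundaries aligned to baseline + window grid); removes all
    #: within-trial correlation — the control condition for leakage studies
    segment_iid: bool = False
    iid_window_seconds: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_subjects, self.n_trials_per_subject, self.n_eeg_channels, self.n_eog_channels) <= 0:
            raise ValidationError("all counts must be positive")
        if self.trial_seconds <= self.baseline_seconds:
            raise ValidationError("trial_seconds must exceed baseline_seconds")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not (0.0 <= self.shared_latent_weight <= 1.0):
            raise ValidationError("shared_latent_weight must lie in [0, 1]")
        if self.eeg_snr < 0 or self.eog_snr < 0:
            raise ValidationError("snr parameters must be non-negative")


@dataclasses.dataclass
class GroundTruth:
    """Per-trial latent state emitted alongside the cohort."""

    classes: dict  # (subject_id, trial_id) -> {"valence": 0/1, "arousal": 0/1}
    latents: dict  # (subject_id, trial_id) -> z(t) [n_samples]
    eeg_mix: dict  # (subject_id, trial_id) -> spatial map [n_eeg_channels]
    eog_mix: dict  # (subject_id, trial_id) -> spatial map [n_eog_channels]


def blink_template(fs: float, duration_s: float = 0.3, amplitude: float = 1.0) -> np.ndarray:
    """Raised-cosine eye-blink deflection."""
    n = max(int(round(duration_s * fs)), 3)
    t = np.linspace(0, np.pi, n)
    return amplitude * np.sin(t) ** 2


def inject_blinks(
    eog: np.ndarray,
    rate_hz: float,
    amplitude: float,
    seed,
    fs: float = 128.0,
    channel_gains=None,
) -> np.ndarray:
    """Add blink deflections at Poisson event times; otherwise identity.

    ``channel_gains`` scales the template per EOG channel (vertical leads
    see blinks much larger than horizontal ones).
    """
    if rate_hz < 0:
        raise ValidationError("rate_hz must be non-negative")
    eog = np.asarray(eog, dtype=np.float64)
    out = eog.copy()
    if rate_hz == 0 or amplitude == 0:
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ch, n_samples = out.shape
    duration = n_samples / fs
    n_events = rng.poisson(rate_hz * duration)
    if n_events == 0:
        return out
    template = blink_template(fs, amplitude=amplitude)
    gains = np.ones(n_ch) if channel_gains is None else np.asarray(channel_gains, dtype=np.float64)
    starts = rng.integers(0, max(n_samples - len(template), 1), size=n_events)
    for s in starts:
        hi = min(s + len(template), n_samples)
        out[:, s:hi] += gains[:, None] * template[: hi - s]
    return out


def _band_noise(rng, shape, fs, lo, hi, order=4):
    """Unit-variance band-limited Gaussian noise along the last axis."""
    white = rng.standard_normal(shape)
    nyq = fs / 2.0
    if hi >= nyq:
        hi = 0.99 * nyq
    sos = _sig.butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")
    x = _sig.sosfiltfilt(sos, white, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _ar2_latent(rng, n_samples, fs, f0=1.5, r=0.99):
    """Smooth band-limited AR(2) latent, unit variance."""
    a1 = 2 * r * np.cos(2 * np.pi * f0 / fs)
    a2 = -(r**2)
    e = rng.standard_normal(n_samples + 4 * int(fs))
    z = _sig.lfilter([1.0], [1.0, -a1, -a2], e)[-n_samples:]
    sd = z.std()
    return z / (sd if sd > 0 else 1.0)


def _trial_signals(rng, spec: CohortSpec, n_samples: int, c_val: int, c_aro: int, m_eeg, m_eog):
    """Synthesize one contiguous stretch of a trial's EEG, EOG and latent."""
    fs, w = spec.fs, spec.shared_latent_weight

    # shared latent: smooth base + class-dependent narrow-band components,
    # one per affective dimension (theta-band for valence, delta for arousal)
    z0 = _ar2_latent(rng, n_samples, fs)
    zeta_v = _ar2_latent(rng, n_samples, fs, f0=6.0, r=0.97)
    zeta_a = _ar2_latent(rng, n_samples, fs, f0=3.0, r=0.97)
    z = (
        z0
        + _CLASS_LATENT_SCALE * np.sqrt(spec.eeg_snr * c_val) * zeta_v
        + _CLASS_LATENT_SCALE * np.sqrt(spec.eeg_snr * c_aro) * zeta_a
    )

    # --- EEG: band-power class signal + shared latent + noise ------------
    alpha = _band_noise(rng, (spec.n_eeg_channels, n_samples), fs, 8.0, 13.0)
    beta = _band_noise(rng, (spec.n_eeg_channels, n_samples), fs, 14.0, 30.0)
    a_gain = _ALPHA_AMP * np.sqrt(1.0 + spec.eeg_snr * c_val)
    b_gain = _BETA_AMP * np.sqrt(1.0 + spec.eeg_snr * c_aro)
    eeg = (
        a_gain * alpha
        + b_gain * beta
        + w * _SHARED_AMP * m_eeg[:, None] * z[None, :]
        + spec.noise_sd * rng.standard_normal((spec.n_eeg_channels, n_samples))
    )

    # --- EOG: drift + blinks class signal + shared latent + noise --------
    # drift occupies 0.15-0.45 Hz: slow eye wander whose correlation dies
    # within a window, so within-trial correlation beyond a window length
    # is attributable to the shared latent
    d_gain = _DRIFT_AMP * np.sqrt(1.0 + spec.eog_snr * c_aro)
    drift = d_gain * _band_noise(rng, (spec.n_eog_channels, n_samples), fs, 0.15, 0.45, order=2)
    eog = (
        drift
        + w * _SHARED_AMP * m_eog[:, None] * z[None, :]
        + spec.noise_sd * rng.standard_normal((spec.n_eog_channels, n_samples))
    )
    blink_rate = _BLINK_BASE_RATE * (1.0 + spec.eog_snr * c_val)
    # vertical lead (index 1 by convention) sees blinks full-scale
    gains = 0.3 * np.ones(spec.n_eog_channels)
    if spec.n_eog_channels > 1:
        gains[1] = 1.0
    eog = inject_blinks(eog, blink_rate, _BLINK_AMP, rng, fs=fs, channel_gains=gains)
    return eeg, eog, z


def generate_cohort(spec: CohortSpec):
    """Draw a full cohort; bit-reproducible from ``spec.seed``.

    Returns ``(recordings, ground_truth)``.
    """
    fs = spec.fs
    n_samples = int(round(spec.trial_seconds * fs))
    baseline = int(round(spec.baseline_seconds * fs))
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)

    recordings: list[Recording] = []
    gt = GroundTruth(classes={}, latents={}, eeg_mix={}, eog_mix={})
    w = spec.shared_latent_weight

    for si in range(spec.n_subjects):
        subj = f"s{si:02d}"
        trial_seeds = subject_seeds[si].spawn(spec.n_trials_per_subject)
        for ti in range(spec.n_trials_per_subject):
            rng = np.random.default_rng(trial_seeds[ti])
            key = (subj, f"t{ti:02d}")

            c_val = int(rng.random() < spec.class_balance)
            c_aro = int(rng.random() < spec.class_balance)

            # per-trial random spatial maps of the shared latent
            m_eeg = rng.standard_normal(spec.n_eeg_channels)
            m_eog = rng.standard_normal(spec.n_eog_channels)

            if spec.segment_iid:
                win = int(round(spec.iid_window_seconds * fs))
                bounds = [0, baseline] if baseline else [0]
                while bounds[-1] < n_samples:
                    bounds.append(min(bounds[-1] + win, n_samples))
                parts = [
                    _trial_signals(rng, spec, hi - lo, c_val, c_aro, m_eeg, m_eog)
                    for lo, hi in zip(bounds[:-1], bounds[1:])
                    if hi > lo
                ]
                eeg = np.concatenate([p[0] for p in parts], axis=-1)
                eog = np.concatenate([p[1] for p in parts], axis=-1)
                z = np.concatenate([p[2] for p in parts], axis=-1)
            else:
                eeg, eog, z = _trial_signals(rng, spec, n_samples, c_val, c_aro, m_eeg, m_eog)

            ratings = {
                "valence": float(rng.uniform(6.0, 9.0) if c_val else rng.uniform(1.0, 5.0)),
                "arousal": float(rng.uniform(6.0, 9.0) if c_aro else rng.uniform(1.0, 5.0)),
            }

            recordings.append(
                Recording(
                    subject_id=subj,
                    trial_id=key[1],
                    eeg=eeg,
                    eog=eog,
                    fs=fs,
                    ratings=ratings,
                    baseline_samples=baseline,
                )
            )
            gt.classes[key] = {"valence": c_val, "arousal": c_aro}
            gt.latents[key] = z
            gt.eeg_mix[key] = m_eeg
            gt.eog_mix[key] = m_eog

    # invariant: re-binarized ratings recover the planted classes
    for rec in recordings:
        for dim in ("valence", "arousal"):
            assert binarize_rating(rec.ratings[dim], LabelSpec(dim)) == gt.classes[rec.key][dim]
    return recordings, gt
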
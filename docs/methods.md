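# Methods

`emokd` implements cross-modal knowledge distillation for affective decoding
from physiological signals: a multimodal EEG+EOG teacher is trained first,
and an EOG-only student is then trained to match the teacher's soft outputs
and fused features, with an optional bilevel feedback loop that adapts the
teacher to the student during distillation. This note records the model, its
assumptions, the numerical choices, and what the synthetic benchmarks do and
do not show.

## Data model and protocol

The unit of acquisition is a *trial*: one stimulus presentation recorded as
32-channel EEG plus 2-channel EOG (horizontal, vertical) at 128 Hz, rated
afterwards on continuous 1–9 valence and arousal scales. Ratings are
binarized with a strict cut at 5 (`class 1 iff rating > 5`), giving two
independent binary tasks. Each trial is cut into non-overlapping 4 s windows
(*segments*) after discarding the leading 3 s pre-stimulus baseline; a
trailing remainder shorter than one window is dropped. No baseline-mean
subtraction is applied.

Because consecutive segments of one trial are strongly correlated, the
train/validation/test partition is drawn at the **trial** level in an 8:1:1
ratio, within each subject's own trials (subject-dependent protocol).
Non-divisible counts are apportioned by largest remainder, which is
deterministic and ratio-faithful; 40 trials always split 32/4/4. A
`PartitionedData` container audits every array access so tests can assert
the test partition is read exactly once, at final evaluation.

Resampling to 128 Hz uses polyphase filtering (`scipy.signal.resample_poly`)
with the output length fixed to `round(n · fs_out / fs_in)`; upsampling is
refused unless explicitly enabled.

## Teacher

Each modality passes through its own two-stage convolutional frontend:

1. a temporal stage with kernel `(1, fs/2)` producing a small bank of
   feature maps. The stride equals the kernel, so each half-second patch is
   embedded independently — with this choice both stages reduce to reshapes
   and affine maps, which is exact and fast in the package's autodiff
   engine, and a 4 s segment becomes an 8-step sequence;
2. a spatial stage with kernel `(channels, 1)` collapsing the electrode
   axis into the model width `d`.

Both stages use ReLU and dropout. Biases are initialized to 0.01: small
positive biases keep rectified units alive and keep pre-activations off the
exact ReLU kink when a step's features are fully suppressed (at the kink,
subgradients and finite differences legitimately disagree).

Each embedded sequence, with fixed sinusoidal position encodings added, runs
through its own post-LN transformer encoder (default 2 layers). The
mean-pooled outputs of layers 1 and 2 of each stream are the four fusion
taps. Mean pooling was chosen for scale stability; a CLS-style alternative
was considered and rejected to keep the sequence length minimal.

**Interaction fusion.** Per tap depth, the EOG and EEG tap vectors are
concatenated (width `2d`) and scored by a gated two-layer extractor,
`score = σ(FC2(δ(FC1(x))))` with hidden width `2·(2d)`, the score
multiplying the input element-wise; the two gated vectors are summed. The
classifier head (affine → softmax) reads the fused feature only. At full
scale the extractor widths (interaction 1024→512, heterogeneous 512→256)
close only with `d = 256` — the element-wise gate forces the scorer's
output width to equal its input width; all widths are configurable and the
synthetic benchmark uses `d = 32`.

## Student

The student mirrors one teacher stream over EOG only, with a 3-layer
encoder — one mean-pooled tap per layer — fused by three gated
heterogeneous extractors (input width `d`, hidden `2d`) and classified from
the fused feature. An affine projection maps the fused feature (width `d`)
to the teacher's fused width (`2d`) for feature matching; when the widths
already agree the projection can be disabled. Which teacher feature the
matching targets is genuinely open; the default pairs fused-to-fused
(widths and roles correspond), with tap-to-tap matching available behind
`align_mode="taps"`.

## Distillation objective

With ground-truth one-hot `y`, student probabilities `ŷ`, teacher
probabilities `y′`, aligned student feature `F_S` and teacher fused feature
`F_T`:

    L_S = λ1·CE(y, ŷ) + λ2·KL(y′ ‖ ŷ) + λ3·MSE(F_S, F_T),   λ1:λ2:λ3 = 1:1:1

The KL term is the standard non-negative divergence with the teacher as
reference. Probabilities are clipped to `[1e-12, 1]` before logs, so the
loss is always finite. Temperature defaults to 1; with `T ≠ 1` both
distributions are re-softened from logits and the term scaled by `T²`.
Ground-truth labels drive the CE term by default; teacher-argmax
pseudo-labels are available behind a flag.

## Two-phase training with dynamic feedback

Training alternates:

* **Teaching phase** — Adam steps on `L_S` update only the student
  (`θ_s`); the teacher is bitwise frozen (hash-asserted every phase).
* **Feedback phase** — a temporary student `θ_ts = θ_s − α ∂L_S/∂θ_s` is
  formed from one plain-gradient inner step on a *training* batch (the
  teacher's outputs stay in the graph), and the teacher descends
  `CE(y_V, f_s(x_V; θ_ts)) + λt·CE(y_V, f_t(x_V; θ_t))` on a *validation*
  batch, with one Adam step per invocation. Using validation data for the
  outer step keeps the training partition from leaking into the teacher
  adaptation; the student proper stays bitwise frozen. Defaults: one
  feedback cycle per epoch after a 5-epoch warmup, α = 1e-3, λt = 1.

The outer gradient is exact second-order by default: the engine's
vector-Jacobian products are themselves differentiable, so the dependence
of `θ_ts` on `θ_t` through the inner gradient is differentiated through,
and with α = 0 the outer gradient reduces bitwise to `λt·∇CE(teacher)`. A
first-order mode detaches the inner gradient, dropping that pathway (the
teacher is then driven by its own CE alone); it is exposed for cost
comparisons. Both models run in evaluation mode (dropout off) during
feedback so the bilevel gradient is deterministic.

Two properties of the update matter in practice. First, the
student-through-step term scales with α: at α ≈ 1e-3 it is numerically
negligible next to the teacher's own CE gradient, so the benchmark uses
α = 0.05 with four cycles per epoch after a 3-epoch warmup (the dataclass
defaults keep the conservative single-cycle schedule). Second, the update
is **guarded** by default: after the Adam step the outer objective is
re-evaluated (fresh inner step included) and an update that worsened it is
reverted, optimizer state and all. A single unguarded stochastic step is
as likely to harm the guidance as to help it at desk scale; guarded
descent makes the feedback phase's expected effect non-negative — when
every update is rejected, the run falls back to the static-teacher
trajectory exactly.

Ablation variations: **V1** — λ3 = 0, no feedback (classic logit-only
soft-label distillation); **V2** — full `L_S`, static teacher; **V3** —
full `L_S` plus feedback. V3 with zero feedback cycles is exactly V2, and
V2 with λ2 = λ3 = 0 is plain supervised training.

## Autodiff engine

No pre-installed package provides differentiable neural networks, and the
feedback phase needs gradients *through* gradients, so the package includes
a compact tape-based reverse-mode engine over float64 numpy arrays
(`emokd.nn`). Every primitive's backward pass is written in the engine's
own primitives, making `grad(..., create_graph=True)` yield differentiable
gradients — the exact second-order feedback update falls out of this design
rather than being approximated. Softmax subtracts a detached row maximum
(value- and derivative-preserving); attention, layer norm and the losses
are composites of the primitives. Gradient audits against central finite
differences cover every primitive, the end-to-end objective (relative error
< 1e-4) and the bilevel outer gradient (< 1e-3).

## Synthetic cohorts

The generator emulates a DEAP-style experiment: per-subject trials of
simultaneous EEG+EOG with 1–9 ratings drawn uniformly from the class's half
of the scale (class 1 → [6, 9], class 0 → [1, 5], recovering the planted
class exactly under the strict >5 cut). Class signal is planted where each
modality physiologically carries it:

* **EEG** — alpha-band (8–13 Hz) amplitude shifts with the valence class
  and beta-band (14–30 Hz) amplitude with the arousal class, both by a
  factor `sqrt(1 + eeg_snr·c)` over band-limited Gaussian oscillations;
* **EOG** — blink rate (Poisson events with a raised-cosine template,
  vertical lead full-scale) shifts with valence and slow-drift power with
  arousal, scaled by `eog_snr`.

A smooth AR(2) latent `z(t)` is mixed into both modalities through
per-trial random spatial maps with strength `shared_latent_weight`. It
serves three purposes: it is the cross-modal common component a multimodal
model can exploit; its per-trial spatial map is the trial-persistent
fingerprint that makes segment-level splitting leak; and it carries
narrow-band components — theta (6 Hz) for valence, delta (3 Hz) for
arousal — with amplitude `∝ sqrt(eeg_snr·c)`: the pathway by which
EEG-borne class evidence reaches EOG, and the substrate the distillation
benefit operates on. Either `eeg_snr = 0` or `shared_latent_weight = 0`
removes that leak. The EOG drift is band-limited
to 0.15–0.45 Hz so its correlation dies within a window and carries no
trial fingerprint of its own. A `segment_iid` switch draws every stochastic
process independently per window (boundaries aligned to the baseline +
window grid) — the control condition for leakage studies.

The generator does **not** attempt biophysical realism: no head model or
electrode geometry, no artifacts beyond blinks, stationary class-conditional
spectra, and independence across trials. Passing benchmarks therefore show
that the machinery behaves as specified under known ground truth — not that
comparable accuracies would be obtained on real recordings.

## Benchmark problem sizes and expectations

The standard distillation benchmark uses 20 subjects × 20 trials × 19 s
(4 windows per trial, 1600 segments; per-subject split 16/2/2 trials),
`eeg_snr = 2.0`, `eog_snr = 0.5`, `shared_latent_weight = 0.7`, compact
models (`d = 32`, 4 heads, feed-forward 64, dropout 0.1) and short budgets
(12 epochs, batch 64, Adam 3e-3) — sized so the full five-seed,
two-dimension ablation runs in minutes on one CPU core. Under these
conditions the teacher reaches high test accuracy from EEG band power while
the student is limited to what EOG carries; distillation closes part of
that gap, and mean accuracies order V3 ≥ V2 ≥ V1 in at least one dimension
(pilot runs put V3 − V1 around 3–5 accuracy points in the dimension with
the most headroom; both the ordering and the margin are seed-sensitive at
this scale, which is why the benchmark averages five seeds).

The leakage benchmark uses a weaker-signal cohort (10 subjects,
`eeg_snr = 0.8`) so neither regime saturates, trains identical multimodal
models under trial-wise and segment-shuffled splits of the same segment
pool (equal partition sizes), and evaluates the **final-epoch** model:
best-checkpoint selection on a leaky validation set would otherwise
confound the regime comparison. The correlated cohort shows a positive
inflation gap (pilot mean ≈ +10 points); the `segment_iid` control shows
none beyond sampling noise, whose seed-to-seed spread (a few points with
~30 test trials per split) is why the control mean is averaged over extra
seeds.

## Degenerate inputs and numeric conventions

All computation is float64. Gates are strictly inside (0, 1); zero
extractor parameters gate exactly 0.5. Attention over a single position
returns the value row exactly. Splits of fewer trials than partitions,
ratings outside [1, 9], negative loss weights, α < 0, non-normalized
probability vectors (row sums off by more than 1e-3) and mismatched feature
widths are rejected with named errors. Checkpoints are plain `.npz`
parameter archives; reloading reproduces evaluation losses to better than
1e-6 (exactly, up to float64 round-trip).

## Known limitations

* The engine is single-threaded numpy; full-scale widths (`d = 256`) are
  supported but slow — the package's experiments are desk-scale by design.
* The feedback phase differentiates through a single inner step, not an
  unrolled trajectory.
* Only the two-tap teacher / three-tap student geometry is implemented;
  tap counts are fixed by the architecture, not configurable.
* Accuracies on real recordings (e.g., the DEAP dataset the loader
  supports) require the full-scale models and the external data and are not
  reproduced here; the synthetic benchmarks are directional analogues under
  known ground truth, not replications of any published figure.
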
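# Methods

This note documents what `gazelapse` computes, the modeling assumptions
behind it, the numerical choices that matter, and where the synthetic data
stops being a substitute for real recordings.

## Problem

Given a monocular gaze stream sampled at 100 Hz — `timestamp, x, y, pupil,
confidence` — the package predicts whether the person is currently in an
attention lapse ("forgetting" a monitored item) or operating normally. The
prediction unit is an *event sequence*: six consecutive 5-second windows of
the stream, each summarized by 44 eye-movement metrics.

## Pipeline

### Missing-data repair

Two kinds of missing samples are distinguished before any event detection:

* **Blinks**: runs of missing pupil samples at zero confidence lasting
  50–500 ms. The pupil channel is linearly interpolated across the run
  (nearest-value extension at recording edges); gaze coordinates during a
  blink are kept but flagged, and no fixation may span a blink.
* **Collection dropouts**: any other missing sample. Each is replaced by
  the mean of the valid samples within ±10 samples (±100 ms). A run with no
  valid neighbour in that radius cannot be repaired and raises an error
  rather than silently propagating.

### Windowing and labels

Windows are 500 samples (5 s) long; adjacent windows share 100 samples
(stride 400). A window is labeled *lapse* when at least half of its span
overlaps an annotated lapse episode, *normal* otherwise. Sequences of 6
consecutive windows inherit the label of their final window and never span
recording boundaries.

### Oculomotor events

* **Fixations** come from a dispersion-threshold (I-DT) pass: a candidate
  span of at least 0.1 s grows while its spread, measured as
  `(max x − min x) + (max y − min y)`, stays within 30 px. Detection runs
  independently on each eyes-open span.
  *Merge rule*: adjacent detections separated by at most 2 samples whose
  centroids lie within the dispersion threshold (and with no blink between)
  are merged into one fixation. Without this rule, the slow tail of a
  minimum-jerk saccade occasionally glues onto the start of a dwell, pushes
  the running dispersion over threshold mid-fixation and splits one physical
  fixation in two; a genuine saccade moves the centroid far beyond the
  threshold, so real transitions are never merged.
* **Saccades** are derived between consecutive fixations not separated by a
  blink; endpoints are the fixation centroids. A zero-sample gap (two
  dwells split exactly at the dispersion boundary) is assigned one sample
  period (10 ms) of duration so saccade speed stays finite.
* **Blinks** are the repaired blink runs, bounded to 50–500 ms.

### Features

Each window yields 23 *time-related* metrics (quantities that accumulate
with time: counts, totals, rates — e.g. fixation count, total saccade
length, blink rate, mean pupil diameter) and 21 *time-independent* metrics
(distributional and spatial statistics — e.g. median fixation duration,
duration skewness, scanpath length, grid-based noting/returning counts).
The exact definitions are frozen in the exported name manifests in
`gazelapse.features`. Conventions:

* standard deviations are population (n-denominator); skewness is Fisher,
  kurtosis is excess, both biased; third/fourth moments fall back to 0 below
  three observations, so every metric is finite for every window;
* "noting" counts first visits to cells of a 4×4 screen grid, "returning"
  counts refixations on an already-visited cell;
* the global/local ratio compares saccades above vs below 100 px amplitude.

Features are min-max normalized into [0, 1]; the minima and maxima are
fitted on the training split of each cross-validation fold only, validation
rows are clipped into [0, 1], and features whose training range collapses
map to 0.

## Classifier

The full model is a dual-branch network over a `(6, 44)` sequence, split
into its 23 time-related and 21 time-independent columns:

* **Time-related branch**: three temporal convolution blocks
  (kernel length 2 along the event axis, 64 channels, causal zero-padding,
  no bias, each followed by batch normalization and ReLU) map `(6, 23)` to
  `(6, 64)`; the deep features are *spliced* with the raw features to
  `(6, 87)`, batch-normalized, fed to a 3-layer LSTM with hidden width 128,
  and the final step's hidden state is projected to a length-2 vector.
* **Time-independent branch**: the same convolution stack on `(6, 21)`,
  flattened and projected to a length-2 vector.
* **Fusion**: the two length-2 outputs are concatenated and a final dense
  layer produces the class logits; softmax gives P(normal), P(lapse). A
  tied 0.5/0.5 prediction resolves to *normal*.

Two ablations keep everything else identical: *conv-only* drops the LSTM
(splice → batch norm → flatten → head) and *recurrent-only* feeds the raw 23
features straight into the LSTM. The linear baseline is binary logistic
regression on the per-sequence mean of the same 44 normalized features,
fitted by Newton/IRLS to tolerance 1e-8 (with a weakly regularized fallback
when the fold is perfectly separable).

All layers are implemented in NumPy with hand-written forward and backward
passes; analytic gradients are validated against central finite differences
in the test suite. Weights use He initialization (normal with variance
2/fan-in); biases start at zero. Training uses Adam (learning rate 1e-4,
β₁ = 0.9, β₂ = 0.999, ε = 1e-8, bias-corrected) with batch size 64 and
per-epoch reshuffling.

## Cross-validation protocol

Sequences are assembled at stride 1, so neighbours share 5 of their 6
windows. Shuffling sequences across folds therefore places near-duplicates
of training rows — with identical labels — into validation, which we
measured to inflate even a logistic baseline far above chance on label-free
data. Folds are instead formed from **whole recordings** (5 folds, each
holding out one or more recordings), so overlapping sequences never straddle
a train/validation split. This also matches the deployment question: can
the model score a person it was not trained on? Min-max normalization and
model initialization are redone per fold; all methods share one fold
assignment per run, enforced by a fold checksum.

Benchmark datasets are balanced by seeded subsampling of the majority class,
so accuracy has chance level 0.5.

## Synthetic data

No public gaze-with-lapse-annotation corpus exists at the fidelity this
pipeline needs, so a seeded simulator provides ground truth:

* **Scanpath**: gaze rests on one of 12 uniformly placed screen targets;
  dwell durations are lognormal (median 0.3 s, σ = 0.35 in log-space);
  transitions are minimum-jerk trajectories with peak speed 18,000 px/s and
  duration proportional to distance.
* **Blinks**: a Poisson process (15/min) of 0.1–0.3 s closures, written as
  missing pupil samples at zero confidence.
* **Noise**: AR(1) pupil fluctuation (φ = 0.95) plus white positional
  jitter; rare single-sample collection dropouts (rate 5e-4).
* **Lapse episodes**: spans drawn at a configurable rate (default 6/h,
  20–60 s long) during which fixation durations and saccade amplitudes are
  multiplied by 2, blink rate is doubled and pupil diameter shifts by
  +0.5 mm. With all multipliers at 1 and shift 0 the generator consumes
  random numbers identically to the no-episode case, so "null" data differs
  from signal data only through the episode effects.

Scope and limits: the simulator produces plausible *statistics*, not
plausible *behavior*. Targets are static and revisited at random; there is
no task structure, no smooth pursuit, no head movement, no calibration
drift, and the lapse effects are stylized step changes rather than gradual
physiological drift. Accuracies measured on this data characterize the
pipeline — that the architecture can learn temporally structured effects of
this size, and that the protocol is leak-free — and do not transfer to any
claim about real operators.

## Numerical choices

* float32 weights/activations for training speed; float64 for all oracle
  checks and gradient verification.
* Batch-norm ε = 1e-5; running statistics with momentum 0.1 for inference;
  training-mode batch norm requires at least two rows, so size-1 trailing
  minibatches are skipped.
* The finite-difference gradient check uses central differences with
  eps = 1e-6 and relative error `|num − ana| / max(|num| + |ana|, 1e-4)`;
  the 1e-4 guard reflects the resolution limit of the difference quotient
  for an order-one loss (gradients below ~1e-4 in magnitude cannot be
  resolved relatively and would otherwise register pure rounding noise).
* Sequence seeds everywhere: recordings, fold shuffles, model
  initializations and subsampling all derive from `numpy` `SeedSequence`
  spawns of one user-supplied seed, so every artifact is reproducible
  bit-for-bit on one machine.

## Benchmark problem sizes

The reproduction script (`scripts/acceptance.py`) and the heavyweight test
use two fixed regimes chosen to fit a single CPU budget of roughly fifteen
minutes:

* *signal*: 10 recordings × 1500 s at 12 lapses/h, ~1000 balanced
  sequences, 30 training epochs, five seeds;
* *null*: 5 recordings × 600 s with unit effect multipliers, 10 epochs,
  five seeds.

Each regime reports per-seed mean cross-validated accuracy for all four
methods, plus how often the expected ordering (hybrid ≥ best ablation ≥
logistic) holds across seeds. The hybrid-vs-ablation comparison is a
stochastic property of this synthetic task and is reported per seed rather
than asserted: on data this cleanly separable, the raw 23 features are
already near-sufficient for the LSTM, and the convolutional front-end adds
no measurable margin (see `README.md` for measured values).

## Limitations

* Synthetic-only validation; no human data is included or emulated at the
  level of individual differences, fatigue dynamics or task load.
* The label rule (≥50 % episode overlap) makes window labels, and hence
  sequence labels, sharp; real annotations are noisier.
* Single-machine determinism only: results are reproducible for a fixed
  seed, BLAS and NumPy version, but bit-level results may differ across
  platforms.
* The logistic baseline sees per-sequence mean features; richer classical
  baselines (e.g. gradient boosting on all 264 values) were out of scope.
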
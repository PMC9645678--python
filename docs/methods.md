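# Methods

## Problem setting

A forearm armband records eight dry-electrode sEMG channels and a 6-axis IMU
(3-axis accelerometer in g, 3-axis gyroscope in deg/s), every channel at
200 Hz, sEMG quantized to signed 8-bit integers.  The task is window-level
binary classification: does a 10 s window of the stream belong to a cigarette
smoking session?  Evaluation is leave-one-subject-out (LOSO), so the model
must generalize to an unseen person.

## Synthetic cohort generator

The generator emulates the *structure* of a supervised validation study, not
any particular recording.  Each subject performs ten ordered activities:
reading, slow and fast treadmill walking, resting, smoking while sitting,
phone talking, eating, smoking while walking and talking, smoking while
sitting and talking, smoking while walking silently.  Non-smoking,
non-eating activities are capped at 5 min.  The default protocol gives four
~267 s smoking sessions per subject (the mean session length implied by
4.75 h of smoking across 64 events); the "easy" protocol compresses the same
schedule to ~23 min per subject.

Signal model (all draws from one seeded generator per subject, spawned
deterministically from the cohort master seed):

* **sEMG.** Channel *c* is `round(clip(A_c(t) · n(t)))` with `n(t)` zero-mean
  Gaussian noise band-passed to 20–95 Hz (inside the 100 Hz Nyquist of the
  200 Hz rate) and rescaled to unit variance.  The amplitude is
  `A_c(t) = baseline · (1 + (burst_gain − 1) · w_c(t))`, where `w_c(t)` is
  the activity's per-channel activation weight — engaged during puff/bite
  gestures for smoking/eating and throughout the interval for sustained
  activities.  Baseline is 3 quantization counts; the default burst gain is
  4 (10 in the easy preset).
* **Gestures.** Puffs last 2–4 s with 20–40 s gaps; eating bites last 1–2 s
  with 8–15 s gaps.  Gesture trains start at the session start and are
  truncated at the session end, so a 267 s session contains 6–13 puffs.
* **IMU.** The accelerometer reads the gravity vector rotated by the
  forearm-pitch trajectory: a raised-cosine bump per hand-to-mouth gesture
  (peak 0.7 rad by default, bites at 75 % of a puff's amplitude) on top of a
  sustained arm-hold offset of 0.35 rad during smoking sessions and 0.30 rad
  during phone talking (trapezoidal, 3 s ramps).  Walking adds a 1.8 Hz gait
  oscillation; white noise (0.02 g, 5 deg/s) is added throughout.  The
  gyroscope carries the pitch rate in deg/s.
* **Between-subject variation.** Each subject draws an amplitude scale
  (±20 %), a per-channel attenuation of the activation profiles (down to
  −30 %), and an armband placement rotation — a circular, fractionally
  interpolated shift of all activation profiles by up to ±1 channel position
  (±0.5 in the easy preset).

These choices produce the *complementary-modality* structure the pipeline is
meant to study: eating shares part of smoking's sEMG activation profile and
placement rotation makes sEMG the weaker modality across subjects, while
phone use shares smoking's postural IMU cue; only the fused configuration
sees both disambiguating signals, so sensor fusion genuinely helps under
LOSO.  Not emulated: biomechanical muscle dynamics, motion artifacts and
electrode lift-off, magnetometer output, free-living behavior, or realistic
inter-activity breaks.  Passing benchmarks on this generator therefore show
that the pipeline's machinery is correct and that it can exploit such
structure — not that any particular performance level would transfer to real
recordings.

## Windowing and labeling

Windows are `floor((T − W)/S) + 1` fixed-length segments (defaults W = 10 s,
S = 5 s); trailing samples that do not fill a window are dropped so every
tensor has the same shape, and windows never straddle recording boundaries.
A window is labeled smoking when the fraction of its span inside the union
of smoking-class events reaches `min_overlap_fraction`.  The default 0.5
avoids labeling windows dominated by non-smoking content at session edges;
setting the threshold near 0 recovers the "any overlap counts" reading.
All four smoking activities count as smoking.

## Spectrogram imaging

Defaults: 512-point FFT over 256-sample Hamming frames at 95 % overlap
(hop = `max(1, round(256 · 0.05))` = 13), no edge padding, one-sided
magnitudes.  A 2000-sample window yields a raw 257 × 135 array; the stated
analysis parameters and the fixed 256 × 112 image shape are arithmetically
incompatible, so a conforming step closes the gap explicitly: the redundant
Nyquist row is dropped when the raw frequency axis is exactly one bin over
target (otherwise the axis is linearly resampled), and the time axis is
always linearly resampled to 112 bins.  Log scaling uses 20·log10 with a
−120 dB floor, so silent channels are finite.  Per-channel z-scoring is
fitted on training folds only and applied to the held-out subject — the
LOSO purity audit in the test suite verifies this.

## CNN-LSTM

Three conv blocks (conv → batch-norm → ReLU → max-pool) with feature maps
128/64/32.  Each conv filter spans `max(1, floor(0.5 · input_dim))` per
spatial axis (valid mode, stride 1); for a 256 × 112 input the first filter
is 128 × 56.  Pooling is non-overlapping 2 × 2 with trailing partial windows
kept (output dim `ceil(d/2)`), which keeps small feature maps well-defined;
with floor truncation the three-block stack would be undefined below roughly
21 pixels per axis.  A fully connected layer (linear — no nonlinearity is
interposed before the recurrence) reduces each window to 32 features,
followed by 0.5 dropout.

The recurrence consumes **per-window features, not intra-window time bins**:
sequences of 6 consecutive windows (≈ 35 s of context, padded by repeating
the first window at recording starts and flagged) pass through two LSTM
layers of cell size 64, and a single sigmoid unit on the final step yields
the smoking probability of the sequence's last window, so every window gets
exactly one prediction.  Loss is binary cross-entropy on logits; the
operating point is fixed at 0.5 (no threshold tuning).

Training: Adam, learning rate 10⁻², mini-batch 64 sequences, 5 epochs.
Mini-batches are contiguous blocks of sequences with the block order
shuffled each epoch: overlapping sequences in a block share windows, so each
window's CNN pass is computed once per batch and its feature gradient
scatter-accumulated — a ~5× saving that leaves the objective unchanged.
Everything is float64; convolution is im2col + GEMM; all layers pass central-
difference gradient checks.  Seeded runs are bit-reproducible within one
environment; exact cross-environment bit determinism is not promised.

## Channel selection

SFS grows an sEMG subset greedily: each step trains and scores the
classifier with every remaining candidate appended and keeps the argmax of
the criterion (F1 by default, accuracy available), ties breaking to the
lowest channel index.  Scoring defaults to a grouped subject-wise holdout
(one third of subjects held out) because full LOSO inside SFS is quadratic
in subjects × channels; full-LOSO scoring remains available.  The wrapped
classifier is pluggable: the CNN-LSTM at reduced epochs, or a logistic
regression on per-channel spectrogram mean/sd summaries for fast selection
and testing.  `best_subset` returns the highest-scoring prefix (earliest on
ties), which can be smaller than the full channel set.

## Evaluation and statistics

Per-fold confusion matrices are accumulated element-wise.  Metrics are
reported under both conventions, labeled explicitly: **micro** (from
accumulated counts) and **macro** (mean of per-fold metrics).  The embedded
reference table illustrates why: only six of its sixteen printed values
match a micro-computation from its own printed counts (e.g. the all-8-channel
F1 prints 0.70 where the counts give 0.7296); the package flags such rows
rather than forcing either reading.  Zero-denominator metrics return 0 with
a `degenerate` flag; an all-zero matrix is an error.

McNemar's paired test uses the discordant counts *b* (A right, B wrong) and
*c* (the converse) with an exact two-sided binomial p at rate ½ — valid at
all counts, including the near-zero-p regime — plus a continuity-corrected
chi-square variant for large *b + c*.  The chi-square approximation tracks
the exact p closely when the discordances are near-balanced (the null);
under extreme imbalance it can deviate by far more than 10 %, which is why
the exact form is the default.

## Benchmark problem sizes

The end-to-end LOSO benchmark (`presets.run_easy_benchmark`) uses 8 subjects
on the ~23-min easy protocol (≈ 275 windows/subject, 2200 windows total),
three sensor configurations (sEMG, IMU, fused), and default model/training
configs, with a compact spectrogram image — 12 × 8 bins from a 32-point FFT
at 75 % overlap — as the package's problem-size choice for single-CPU runs;
one seed takes ≈ 150 s.  At this scale the broadband sEMG burst energy and
the low-frequency IMU posture/gesture content survive, which is what the
classifier needs; the full 256 × 112 imaging remains the library default and
its shape contract is tested separately.

## Known limitations

* The benchmark is seed-sensitive: with the high 10⁻² learning rate and only
  5 epochs, an occasional fold trains to a poor operating point, and a
  minority of cohort seeds yield fused micro-F1 below the typical ~0.9
  (observed range across probed seeds ≈ 0.79–0.95).  The packaged checks use
  three fixed seeds; robustness across arbitrary seeds would need a lower
  learning rate or more epochs than the fixed training recipe allows.
* The NumPy implementation is single-threaded BLAS-bound; full-size
  256 × 112 training is impractical on CPU and untested beyond shape and
  gradient contracts.
* The generator's effect sizes are plausible but invented; no quantitative
  claim about real smoking data follows from them (see the generator section
  above).
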
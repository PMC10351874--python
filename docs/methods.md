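# Methods

This note documents the models, defaults and design decisions behind
`myoankle`: what each stage computes, which knobs matter, and what the
synthetic data generator does and does not emulate.

## Synthetic gait generator (`synthetic_gait`)

The generator produces trials with the statistical structure the analysis
assumes, so every downstream stage is testable without recorded data.

**Gait clock.** Stride duration follows a fixed monotone surrogate of the
speed–cadence relation, `stride_time(v) = clamp(1.9 − 0.5·v, 0.8, 1.8)` s,
quantized to the mechanical sample grid. No cadence model is claimed; any
monotone map would serve, and this one is frozen for reproducibility.
Heel-strike events sit at stride boundaries on the mechanical clock
(default 100 Hz); EMG lives on its own faster clock (default 1000 Hz) so
that downstream alignment must be explicit, as with real multi-rate
acquisition.

**Activation envelopes.** Each muscle's envelope is a sum of
circular-Gaussian bursts in %GC (exactly periodic across the 100→0 wrap)
times a monotone speed gain `g(v) = 0.5 + 0.5·v`, plus a tonic baseline.
Burst phasing follows textbook level-walking EMG: TA around heel strike and
in terminal swing, the plantar flexors (SO, MG, PL) through stance into
push-off, RF/VM in loading response and pre-swing, BF around heel strike and
late swing, GMax in early stance. Amplitudes (40–120 µV-like units against
a noise floor of 2) are generator parameters, not claims about any dataset.

**EMG surrogate.** The standard amplitude-modulated band-limited-noise
model: Gaussian white noise band-passed to 10–400 Hz with a 4th-order
Butterworth filter applied forward–backward, normalized to unit sample SD,
multiplied samplewise by the envelope, plus additive noise-floor Gaussian
noise. Nothing is ever rescaled per channel — scaling a muscle's burst
amplitudes by k scales that channel's RMS by k, preserving the
"nonnormalized" property the pipeline is built around.

**Ankle templates.** Angle and moment are deterministic smooth periodic
curves built from circular-Gaussian bumps: dorsiflexion through mid-stance,
a speed-scaled plantar-flexion excursion at push-off (angle), and a
plantar-flexor moment peaking in mid-to-late stance (peak within 30–60 %GC)
with a small post-contact dorsiflexor dip, near zero through swing. The
`push_off_gain` parameter scales the push-off components linearly. Gaussian
bumps in circular phase distance were chosen over a truncated Fourier
series: they are exactly periodic, satisfy every shape requirement directly,
and need fewer coefficients. Small additive measurement noise (0.25 deg,
0.01 Nm/kg SD) emulates motion-capture/force-plate noise; setting it and the
EMG noise floor to zero yields the noise-free regime used for parameter
recovery.

**Speeds.** Trial speeds are jittered-stratified over 0.3–2.3 m/s (one
uniform draw per equal-width bin, bin order shuffled), so both sides of any
reasonable trial-level split cover the full speed range.

**What the generator does not emulate:** motor-unit firing statistics,
electromechanical delay, crosstalk between channels, subject-specific
anthropometrics or template shapes, non-level walking, and non-stationarity
(fatigue). Tests passing on synthetic data therefore demonstrate the
pipeline's correctness and sensitivity, not clinical performance on
recorded gait.

## Feature extraction (`features`)

Five time-domain features (IEMG, MAV, RMS, WL, WAMP) are computed over
causal sliding windows of each raw channel. Defaults:

- **window 150 ms** — inside the sub-300 ms budget required for real-time
  myoelectric control;
- **hop 10 ms** — one mechanical sample period at 100 Hz, so feature rows
  align 1:1 with mechanical samples after the first window of warm-up and no
  resampling stage is needed. The hop is a package choice, exposed in
  `WindowSpec`;
- **WAMP threshold** — data-driven per channel: 3× the median absolute
  deviation of the channel's first 200 ms, clamped below by an absolute
  floor (default 10⁻³ signal units). A fixed absolute threshold would not
  transfer across nonnormalized channels of very different scale. A
  configured absolute value overrides it. Steps exactly at the threshold
  count (|Δ| ≥ threshold).

Windows are end-aligned (each row summarizes only past samples) and
extraction is vectorized with cumulative sums; the test suite verifies
equality with the naive per-window formulas.

## Combinations (`combinations`)

All 2⁵−1 = 31 feature subsets and 2⁸−1 = 255 muscle subsets are enumerated
in (size, lexicographic) order with canonical '+'-joined names (muscle order
TA, SO, MG, PL, RF, VM, BF, GMax; feature order IEMG, MAV, RMS, WL, WAMP).
The lower-leg group is {TA, SO, MG, PL}, the upper-leg group
{RF, VM, BF, GMax}. No heuristic subset search is provided: the analysis is
exhaustive by design.

## Predictors (`predictor`, `_lstm`)

Two separate single-output regressors — ankle position (deg) and moment
(Nm/kg) — rather than one two-output network, keeping each model small and
independently tunable. Each is a **single LSTM layer plus a linear head**,
implemented in numpy (float64 throughout, gate order i/f/g/o, forget-gate
bias +1, Glorot-style uniform initialization seeded per model). Depth
beyond one layer is deliberately out of scope; the hidden-unit count is the
tuned capacity knob (defaults 200 position / 50 moment, sweepable to 250
via `hidden_unit_sweep`, ties resolved toward fewer units).

Training: Adam (lr 10⁻³, β = 0.9/0.999), MSE loss, 200 epochs by default,
global gradient-norm clipping at 1.0 for stability. Inputs and the target
are z-scored by training-set statistics; zero-variance columns get unit
scale with a warning. The scalers are fixed constants of the trained model —
this standardizes network inputs only and does not reintroduce sEMG
amplitude normalization (no reference contraction, no per-trial rescaling).
Trials are cut into non-overlapping truncated subsequences (default 100
rows = 1 s) batched by equal length with seeded shuffling; inference runs
statefully over the full trial sequence. Targets are aligned to feature
rows by linear interpolation of the mechanical series at each window end
time.

Splits are random at the trial level (never within a trial), training share
`round(fraction·n)` clamped so both sides are non-empty.

## Evaluation (`evaluation`)

**%GC grid.** Each complete heel-strike-to-heel-strike cycle is linearly
resampled onto 100 nodes at 1..100 % of cycle duration. The first cycle of
every trial is excluded from evaluation: its opening samples precede the
first complete feature window and carry no prediction.

**Agreement.** Pearson r and RMSE (target units) are computed per validation
trial over its concatenated resampled cycles, then aggregated as mean ± SD
across validation trials. A constant reference makes r undefined and raises
a dedicated error that still carries the RMSE.

**1-D SPM.** Node-wise two-group one-way-ANOVA F (equal to the squared
two-sample t) between the pooled actual and predicted per-cycle curves. The
family-wise critical value is the (1−α) quantile of the max-over-nodes F
under seeded permutations of the group labels (default 1000); this
permutation scheme is self-contained and assumption-light. A parametric
node-wise F threshold with no family-wise correction is available as a
labeled, liberal fallback. Random-field-theory thresholds are not
implemented and no equivalence with them is claimed. When both between- and
within-group variance vanish at a node, F is defined as 0.

**Scores.** miscorrelation = mean deviation of the two correlation means
from 1; RMSE score = mean of the two RMSEs normalized to their peaks over
the *complete* cohort being ranked; SPM score = mean significant-node
fraction; overall error score = exact product of the three (asserted on
every record). Report output is rounded to 4 decimals, round-half-even;
internal arithmetic keeps full precision.

## Ranking and selection (`ranking`)

Cohorts are ranked by ascending overall error score; ties break toward
fewer members, then canonical name (ties do not arise in practice but the
rule keeps runs reproducible). Selection on muscle cohorts:

- eligibility: mean validation r ≥ 0.90 (configurable) for **both** targets;
- **economic**: eligible, minimum muscle count, best rank;
- **flexible**: ranked strictly better than the economic pick, minimum
  lower-leg count, best rank ("performing better" = strictly lower overall
  error score);
- **practical**: eligible, lower-leg count zero, minimum muscle count, best
  rank.

Every filter step is recorded in an audit trail; an exhausted filter raises
an error carrying that audit. No ordering between the economic and flexible
muscle counts is implied by the definitions, and none is asserted.

## Pipeline and I/O (`pipeline`, `io`, `cli`)

One run evaluates exactly one cohort: all 31 feature subsets at a fixed
muscle set (default MG+BF+GMax) or all 255 muscle subsets at a fixed feature
set (default IEMG+WL). Every stochastic stage (data generation, split, per
combination model seeds and permutation seeds) draws its seed
deterministically from the master seed and logs it, so a run is fully
reconstructible from (config, master seed) and ranking CSVs are
byte-reproducible. Trials interchange as long-format CSV (t_s, channel,
value) plus a JSON sidecar; CSV keeps the format dependency-free, and a
reader for other containers is a documented extension point. The `myoankle`
CLI exposes simulate / extract / train / evaluate / rank / report.

## Problem sizes in the test suite

The test suite exercises the full pipeline at deliberately small scales,
chosen as package defaults for fast, deterministic checks: the
parameter-recovery test uses 20 noise-free trials (10 strides each), all 8
muscles with IEMG+WL, 32 hidden units and 5 epochs, and requires mean
validation r ≥ 0.8 for both targets (the observed values are ≈ 0.94 and
≈ 0.97); the end-to-end determinism test ranks the full 31-combination
feature cohort twice on 8 trials of 4 strides at 2 epochs, 8 hidden units
and 200 SPM permutations and requires byte-identical rankings. Larger runs
change accuracy, not behavior.

## Known limitations

- The LSTM trainer is CPU-bound numpy; it is intended for the package's
  analysis scales, not for large-scale training.
- The permutation SPM threshold is not interchangeable with random-field
  theory critical values; significant-node fractions from the two methods
  can differ.
- The synthetic generator's phase-locked, quasi-periodic structure is easier
  to learn than real gait; recovery results bound correctness, not field
  performance.
- Between-combination inferential statistics (e.g., repeated-measures ANOVA
  across combinations) are outside the package's scope; the ranking is
  purely the composite score.
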
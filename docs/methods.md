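# Methods

This note records the scientific and numerical choices behind `gaitshift`:
what the synthetic generator emulates, how each processing stage is
defined, which conventions pin down the neural architectures, and what the
tests do and do not demonstrate.

## The experimental design being modelled

The unit of observation is a *traversal*: one walk of a fixed outdoor route
by one participant under one of six conditions — no goggles, or one of five
vision-distorting goggles whose strap colour encodes a manufacturer-declared
simulated blood-alcohol range. A severity scalar in [0, 1] is assigned to
each condition as the midpoint of its declared range divided by the largest
midpoint (0.305 % BAC for the orange strap):

| condition | declared range (% BAC) | severity |
|-----------|------------------------|----------|
| none      | 0                      | 0.000    |
| green     | 0.04–0.06              | 0.164    |
| blue      | 0.06–0.08              | 0.230    |
| black     | 0.08–0.15              | 0.377    |
| red       | 0.15–0.25              | 0.656    |
| orange    | 0.26–0.35              | 1.000    |

A cohort is 16 participants × 6 conditions = 96 traversals, tri-axial
pocket acceleration at 50 Hz, with cleaned active-walking lengths between
2,293 and 6,211 samples and mean ≈ 3,030. Classification is 6-class over
fixed-length windows, with an 80/20 chronological split *within* each
traversal — a within-subject protocol; nothing here supports claims about
generalisation to unseen participants.

## Synthetic cohort generator

The generator targets the statistical structure a classifier sees, not
biomechanical validity. Per axis, the signal is a sum of two harmonics
driven by a common step phase θ(t) that advances by π per step:

- x (mediolateral): stride-frequency oscillation `a_x sin(θ + φ_x)` plus
  low-pass-filtered sway noise (2nd-order Butterworth, 2 Hz cutoff);
- y (anteroposterior): step-frequency harmonics
  `a_y [sin(2θ + φ_y) + 0.30 sin(4θ + φ_y2)]`;
- z (vertical): `a_z [sin(2θ) + 0.35 sin(4θ + φ_z2)] + 9.81 m/s²`.

Step intervals are Gaussian with participant-level mean (base cadence
uniform on 1.6–2.0 Hz) and a coefficient of variation of 0.025 at baseline.
Inter-axis phase constants are global, and traversal-level randomness is
limited to a global phase shift (equivalent to a time shift), the step
interval realisations, the noise draws and a small random pocket-orientation
rotation (σ = 0.03 rad) applied to the dynamic component only — so under a
null generator (effect scale 0) the six conditions are exchangeable by
construction. Gravity stays exactly on z, matching the simplified
compensation applied downstream. Sensor noise is i.i.d. N(0, 0.08² m²/s⁴)
on all samples, including the 3 s stationary pads that precede and follow
the active region; the trial markers bracket the active region and are
carried in the manifest.

Condition effects are linear in severity with slopes frozen after a single
calibration pass (see *Calibration* below):

- step-time CV multiplier 1 + 8.0·s,
- mediolateral sway amplitude multiplier 1 + 3.2·s,
- cadence multiplier 1 − 0.22·s,
- per-step amplitude irregularity (modulation SD) 1.1·s.

Adjacent severities (green/blue at 0.164/0.230; black/red/orange at
0.377/0.656/1.0) produce overlapping signal statistics, which is what makes
neighbouring conditions the most confusable — the qualitative confusion
structure the real experiment exhibits.

Active lengths are drawn from a truncated exponential above the range
minimum with the scale solved so the truncated mean hits the configured
target; this reproduces the minimum, maximum and mean of the real cleaned
dataset simultaneously (a uniform draw on the range cannot match the mean,
which sits well below the range midpoint).

**What the generator does not emulate:** real device orientation drift,
turning/stopping micro-pauses, surface effects, participant fatigue or
learning across conditions, and any biomechanics beyond harmonic structure.
Passing tests therefore demonstrate the *pipeline's* correctness and the
learnability of severity-scaled gait changes, not performance on real
recordings.

## Preprocessing

Stages run in a fixed order: synchronise → map markers → crop → gravity
offset → periodicity profile → steady-segment extraction.

- **Synchronisation**: linear interpolation of every stream onto one
  uniform axis covering the overlap. Linear is monotone and artefact-free
  at 50 Hz for gait-band signals.
- **Marker mapping**: raw marker indices → timestamps → the first synced
  sample at or after each timestamp.
- **Gravity**: a constant 9.81 m/s² subtracted from z after cropping. No
  orientation normalisation is attempted (a stated limitation of the
  protocol this mirrors).
- **Periodicity**: over 2.56 s (128-sample) windows hopped every 8 samples,
  the score is the maximum normalised autocorrelation of the demeaned
  acceleration magnitude over lags 0.4 s–min(1.5 s, half the window); the
  half-window cap keeps at least 64 samples of overlap in the estimate.
  A window is a *valid gait pattern* when it is a local maximum of the
  score, the score is ≥ 0.4, and its magnitude SD is ≥ 0.2 of the most
  active window's (the activity gate prevents near-stationary noise, whose
  extreme-value autocorrelation can exceed 0.4, from registering as gait).
- **Extraction**: the steady segment spans from the (n_trim+1)-th to the
  (n_trim-from-last)-th valid pattern with n_trim = 3, excluding gait
  initiation and termination; fewer than 2·n_trim+1 patterns or a remainder
  shorter than one model window raises a no-steady-gait error.

Thresholds 0.4 / 0.2 / n_trim 3 are package choices — the procedure they
implement fixes none of them — and are exposed as parameters.

## Window datasets

Per traversal: chronological split at ⌊0.8·T⌋ **before** windowing (the
only reading under which train and test provably share no sample), then
sliding windows of 256 samples with stride 4 on each side independently,
then white-noise augmentation (mean 0, variance 0.2, 10 extra copies per
original) of the training side only. Test counts are invariant to the
augmentation settings. The augmentation factor and variance are
configurable because the source protocol itself reports two variants
(variance 0.1 with 5 copies for one architecture) and its printed training
tensor size is not an integer multiple of 1 + 10 — printed tensor shapes
are therefore never asserted.

Cross-validation mode replaces the fixed final-20 % test chunk with the
i-th of k contiguous chunks of every traversal (k = 5 by default), training
from scratch per fold; fold summaries report mean, sample SD and the
Student-t 95 % half-width t₀.₉₇₅,ₖ₋₁·SD/√k.

## Architectures and training

The five models map [batch × 256 × C] to six unnormalised class scores.
Conventions, fixed by reconciling every printed parameter count:

- Conv1D: 64 filters, kernel **3**, stride 1, same padding, bias, ReLU.
  (The accompanying text mentions kernel 5, but only kernel 3 reproduces
  50,822 / 38,470 / 72,006 and the 192-parameter-per-channel ablation
  steps; the counts win.)
- BiLSTM: one layer, 32 hidden units per direction, two bias vectors per
  direction — 4h(in+h) + 8h parameters per direction, required to hit
  A2's 9,862. The head consumes the concatenated final hidden states
  (64) → dropout 0.2 → affine 64→6 (390 parameters).
- A4's self-attention: 4 heads formed by reshaping the 64-dim features,
  scaled dot-product, residual connection, **no learned projections**
  (zero parameters) and an affine-free LayerNorm — 38,470 is exactly
  conv + BiLSTM + head.
- A5's two attention blocks: learned Q/K/V/output projections (64×64 + 64
  bias each) plus one elementwise-affine LayerNorm per block
  (16,768/block), then an affine-free LayerNorm before the BiLSTM.
- A1: one conv (3→64) → global average pooling → dropout → head = 1,030;
  the printed "×3" for A1 cannot be reconciled with its printed count, so
  the count wins here too.

Training: Adam, learning rate 1.5·10⁻³, batch 32, cross-entropy,
global-norm gradient clipping at 1.0, up to 20 epochs, seeded shuffling and
dropout. Pretraining wraps the conv stem as a masked-prediction
autoencoder: contiguous 8-sample spans covering ≈15 % of time steps are
zeroed, a mirrored convolutional decoder reconstructs the clean input, MSE
over all positions, 3 epochs, decoder discarded. Mask ratio and span are
package choices; the procedure's source names only the family.

The layer stack is implemented directly on NumPy with explicit backward
passes; the test suite verifies every architecture's analytic gradients
against central differences. No deep-learning framework is required at run
time.

Inputs are standardised channel-wise using means and SDs fitted on the
training windows only — standard practice for inertial HAR and necessary
here because the reduced-scale runs afford two orders of magnitude fewer
gradient updates than a full-scale experiment.

## Evaluation suite

One-vs-rest per class: precision, recall, specificity, F1; zero-denominator
cases report 0. Aggregates: accuracy (trace/total), support-weighted F1,
minimum recall, macro F1, class balance = 100·(max − min recall) pp,
average FPR = mean(1 − specificity), and class leakage: off-diagonal
row-normalised percentages rounded to whole numbers, sorted descending with
ties broken by (row, column) class order.

Intervals: Wilson score for accuracy (n = number of test windows — note
that windows are temporally correlated, so this n overstates the effective
information and the interval is optimistic); percentile bootstrap
(B = 1,000 by default, resampling (true, predicted) pairs with replacement,
seeded) for the aggregate indicators; Student-t over folds for
cross-validation. Bootstrap resampling of correlated windows shares the
same caveat as Wilson's n.

## Calibration and the reduced-scale benchmark

The condition-effect slopes were calibrated once — by raising them until a
bidirectional-LSTM (A2) run on a reduced cohort cleanly exceeded twice the
6-class chance level — and then frozen; they are not tuned per seed or per
test. The package's standing benchmark is: 4 participants × 6 conditions,
active lengths 1,900–2,600 samples (mean 2,100; ≈40–50 s of walking),
stride 4, 1 + 2 augmentation at variance 0.2, A2, 5 epochs, fixed seed.
This yields roughly 39–47 % test accuracy across seeds, with training
accuracy still rising monotonically at the last epoch — the model is
deliberately under-trained to keep the benchmark fast; a full-scale run
(16 participants, full lengths, 1 + 10 augmentation, 20 epochs) would sit
substantially higher.

Two controls accompany the benchmark. With all condition effects disabled
(effect scale 0) the same run must stay inside the 95 % binomial band
around 1/6 — computed with the *traversal* count as the effective sample
size, because windows within a traversal are strongly correlated and the
window count would make the band unrealistically narrow. And the calibrated
run must beat the null run, establishing that accuracy comes from the
severity-scaled gait changes rather than generator artefacts
(traversal-identifying randomness is deliberately limited to features that
are label-uninformative under the null).

## Degenerate inputs and numerical details

- Sides of a split shorter than one window contribute zero windows
  (flagged, not an error); an entire dataset without windows is an error.
- Softmax and sigmoid are computed with max-subtraction / argument
  clipping; cross-entropy clips probabilities at 10⁻¹².
- LayerNorm uses ε = 10⁻⁵.
- All randomness flows from a single experiment seed through a stable
  blake2b-based derivation (`derive_seed(seed, stage_label)`), so any stage
  can be reproduced in isolation; derived seeds stay below 2³¹.
- Timestamps are integer milliseconds; the generator jitters the nominal
  20 ms spacing by ±1 ms, which keeps them strictly increasing.

## Known limitations

- Synthetic gait is harmonic, not biomechanical; absolute accuracies on
  this generator say nothing quantitative about real cohorts.
- The within-traversal split measures within-session consistency, not
  subject-independent generalisation (a leave-one-subject-out mode exists
  in the splitter but carries no performance claims).
- Gyroscope channels can be generated for format fidelity but are never
  consumed by the models.
- Interval estimators treat windows as exchangeable units; with overlapping
  strides this overstates precision, which is why fold-level Student-t
  summaries are also reported.
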
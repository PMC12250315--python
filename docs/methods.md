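# Methods

`szforecast` implements a short-horizon neonatal seizure forecasting
pipeline: quantitative EEG (QEEG) features on 20-second epochs, a
convolutional-LSTM sequence classifier for preictal-state probability, an
SPH/SOP alarm system with time-point evaluation, and probabilistic
calibration metrics. A synthetic cohort generator with a plantable
preictal signature makes every stage testable without clinical data.

## Signal model of the synthetic cohort

Each subject's background EEG is 1/f-amplitude-weighted Gaussian noise
(unit-variance pink noise scaled to 30 µV), mixed from a global source, a
per-homologous-pair source and an independent component so that left/right
homologous electrode pairs (Fp1/Fp2, C3/C4, T3/T4, O1/O2 at the default 8
channels) correlate more strongly (~0.58) than non-homologous pairs
(~0.25). Seizures are amplitude-ramped sinusoidal discharges whose
frequency chirps from 3 Hz to 1.5 Hz over the event, superimposed on every
channel with channel-specific phase at 2.5x the background amplitude.
Event counts per affected subject are uniform on {2..6}; durations are
lognormal with median 74 s (log-sd 0.7, clipped to [10, 300] s); events
keep at least 6 min spacing. Three simulated raters annotate 1 Hz binary
masks, optionally with independent uniform boundary jitter; consensus
events are maximal runs where at least k raters agree (k = 2 by default,
k = 1 for single-rater sets).

The planted preictal signature is the ground-truth mechanism the pipeline
must recover: over the `preictal_span` (default 300 s) before each onset, a
linear ramp adds band-limited 8–20 Hz noise (amplitude 0.25 µV-std x
strength at the window end) and inflates signal variance (gain
1 + 0.1 x strength x ramp). Strength 0 makes preictal and interictal
segments statistically exchangeable — the null cohort. The generator
emulates cohort-scale statistics (record length, seizure burden and
duration, multi-rater annotation); it does **not** emulate real neonatal
EEG morphology, artifacts (EMG, electrode pops), state cycling, or
gestational-age-dependent background, so green end-to-end tests
demonstrate mechanism recovery, not clinical performance.

## Preprocessing and labeling

Raw recordings are reduced to a longitudinal bipolar montage (default:
two parasagittal and two temporal chains over the 8-electrode subset),
band-pass filtered 0.1–20 Hz with a 4th-order Butterworth applied
forward-backward (zero phase, so filtering cannot shift preictal timing),
and polyphase-resampled to 40 Hz. When the upper band edge coincides with
Nyquist the filter degrades gracefully to the 0.1 Hz high-pass. All
intervals are half-open `[onset, offset)` seconds.

Epochs are non-overlapping 20 s blocks. Per-second states are assigned
with the precedence **ictal** > **exclusion zones** (60 s before any
onset, 60 s after any offset) > **preictal** (60–360 s before some onset)
> **interictal**; an epoch is ictal if it contains any ictal second and
preictal/interictal only if every second carries that state, excluded
otherwise. The preictal window therefore takes precedence over the
nominal interictal region, keeping the two classes disjoint, and an epoch
covered by the abutting windows of two consecutive seizures still counts
as preictal. Seizures closer than the SPH are merged into one event
before labeling and alarm scoring. Epochs whose look-ahead window
`[end, end + SPH + SOP)` runs past the recording with no intervening
onset are right-censored (outcome unknowable) and excluded.

Training-fold augmentation transposes channels along the left-right and
front-occipital axes (plus the double flip), implemented as involutive
permutations of the bipolar derivations; the front-back flip also carries
a per-derivation polarity sign because reversing a longitudinal chain
negates its derivations. Augmented feature matrices are derived exactly
from the cached per-derivation statistics (summary statistics transform
analytically under negation; spectral and recurrence features are
sign-invariant), which the test suite verifies against re-featurizing the
flipped signals.

## QEEG features

Per epoch and derivation: six summary statistics (mean, population
standard deviation, excess kurtosis, skew, 10th/90th percentiles with
linear interpolation); Welch band powers (4 s segments, 50% overlap) in
the delta/theta/alpha/beta bands truncated at the 20 Hz filter edge
((0.5,4), (4,8), (8,13), (13,20) Hz), emitted as log10 absolute power and
as fractions of total 0.5–20 Hz power (half-open band edges, so the
relative powers over the tiling bands sum to exactly 1); and recurrence
quantification analysis on the x2-downsampled epoch, time-delay embedded
with m = 3, tau = 1, recurrence radius 0.2 x epoch standard deviation
(Euclidean), Theiler window 1: recurrence rate, determinism, laminarity
(line length >= 2) and mean diagonal line length. Left/right derivation
pairs additionally yield asymmetry indices
`(L - R)/(|L| + |R| + 1e-12)` of each summary statistic — bounded,
scale-free, and antisymmetric under the left-right transposition. With
the default montage this gives 4x6 + 8x8 + 8x4 = 120 features in a fixed,
documented column order.

Degenerate conventions (all flagged via logging, never NaN): constant
epochs get kurtosis = skew = 0 and RR = DET = LAM = 1; all-zero epochs get
uniform relative band powers.

## Sequence classifier

The reference model is a ConvLSTM implemented in numpy with hand-derived
gradients (verified against central finite differences): per-time-step
1-D convolution blocks over the feature vector (kernel 3, stride 2,
widths 16/32, ReLU, global average pooling), a single LSTM layer
(hidden 32, forget-gate bias 1), dropout 0.2 on the last hidden state,
and a sigmoid head. Input windows are T = 15 consecutive epochs (5 min,
matching the preictal span) ending at the labeled epoch; windows never
cross subjects or the epoch grid. Training minimizes class-weighted
(inverse-prevalence) binary cross-entropy with Adam (lr 3e-3, batch 256,
float32), early-stopped on validation loss (patience 5, max 30 epochs),
keeping the best-validation parameters. Training is deterministic given
the seed on single-threaded numpy. Classical baselines (logistic
regression, random forest, SVM, k-NN, MLP) run on the flattened window
through the same interface, and further architectures can be registered
as plugins.

Evaluation is subject-stratified nested k-fold cross-validation: test
splits partition the cohort (stratified on the has-seizure flag), the
remainder splits 3:1 into training and validation (67.5/22.5/10% of
subjects at k = 10), validation serving early stopping only. Per-feature
standardization is fit on training subjects only; augmentation applies to
training folds only, with augmented copies inheriting the parent
subject's assignment. Every fold emits a provenance record (subject-ID
sets and hashes for train/validation/test, standardizer fit and
augmentation parents) that the test suite audits for leakage.

## Alarm system and metrics

An alarm triggered when the preictal probability strictly exceeds the
threshold opens a warning of duration SPH + SOP; it is a true positive
iff a merged seizure onsets within `[t + SPH, t + SPH + SOP)`; a seizure
covered by no warning's occurrence period is a false negative. One alarm
is active at a time; the next trigger is eligible at the first epoch
after expiry. All time-based metrics count 20 s grid points on the
evaluable (non-burn-in, non-censored) timeline.

Sensitivity comes in two documented variants: the **event-level** form
(fraction of seizures whose onset fell inside a warning's occurrence
period), used as TPR/recall in threshold sweeps and SPH x SOP grids, and
a **time-point** form (true-alarm time over seizure-associated alarm
time, crediting each missed seizure with the SOP-length trigger window a
correct alarm would have occupied). Corrected time-in-warning is
`(warning time - true-alarm time)/(total time - true-alarm time)`;
precision is true-alarm time over all alarm time; FDR is false alarms
per evaluable hour. Threshold sweeps use 101 evenly spaced thresholds
plus all observed probabilities (grid cells use the even grid alone for
tractability); AUROC integrates TPR against corrected TIW by trapezoid
with (0,0)/(1,1) endpoints, and AUPRC uses step-wise average precision
scanned from high to low threshold to avoid optimistic interpolation.
The positive-class prevalence reported as the AUPRC baseline is the
fraction of evaluable grid time inside some seizure's correct-trigger
window.

Note that the alarm-state ROC is not exactly mirror-symmetric under
probability reversal (triggering is one-sided and suppression reshapes
the alarm sequence); the suite asserts near-symmetry within 0.1.

## Calibration

Reliability tables use 10 equal-width bins on [0,1] (last bin closed);
ECE is the count-weighted mean |accuracy - confidence|. The Brier Skill
Score uses the climatology reference (constant forecast at the positive
prevalence, reference Brier score p(1-p)); single-class label sets report
missing values. Horizon scoring labels a grid point positive iff a
seizure onsets within `[t + SPH, t + SPH + SOP)`, re-derived per grid
cell. No recalibration is applied — the package measures calibration
only. Probabilities are not smoothed before thresholding or calibration
scoring.

## Problem sizes

End-to-end experiments use the default reduced cohort: 12 subjects, half
with seizures, one hour each, 8 channels at 64 Hz, planted strength 2 (or
0 for the null control), with k = 6 folds (two test subjects per fold) —
chosen so the full nested CV runs in minutes on one CPU while keeping at
least one seizure and one seizure-free subject in every split. The
smaller unit-test cohorts (8 subjects, 20 min) additionally raise the RQA
downsampling to x4.

## Known limitations

- The planted signature exists only within `preictal_span` (300 s) of
  onset. Alarm configurations whose correct-trigger window
  `[onset - SPH - SOP, onset - SPH)` lies mostly before that span are
  structurally unpredictable under this generator: grid cells with
  SPH >= ~240 s show near-floor AUROC/BSS with no stable ordering, so
  SPH x SOP trend summaries over the full 1–7 min grid are attenuated
  relative to what a longer-range signature would produce. Longer
  SOP also lengthens warning suppression, which can block a
  correctly-timed trigger after an early false alarm — a real property
  of single-alarm SPH/SOP systems, visible in the grids.
- Event timing is resolved at the 1 Hz annotation grid and metrics at the
  20 s epoch grid; sub-second onset precision is out of scope.
- The ConvLSTM topology is a compact reference realization, not a claim
  of architectural fidelity to any published network; widths and depths
  are configurable.
- The numpy training loop is single-threaded and CPU-oriented; it is not
  intended for large cohorts.
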
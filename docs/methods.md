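# Methods

`sitseg` detects and temporally segments *sit phases* — continuous seated
intervals bounded by stand-to-sit and sit-to-stand postural transitions —
from a single ankle-worn IMU sampling tri-axial acceleration (g) and angular
velocity (deg/s) at 50 Hz. The intended population is people with
Parkinson's disease, for whom ankle placement sidesteps the reduced arm
swing, tremor and dyskinesia that degrade wrist-based activity recognition.

## Signal conditioning

All filtering uses second-order Butterworth low-pass filters applied
forward and backward (zero phase lag; the effective amplitude response of
the double pass is |H(f)|²). Two filtered families are derived per axis:

* acceleration at **0.5 Hz** — isolates the quasi-static gravity component,
  which shifts between two plateaus when the shank tilts into or out of a
  chair. Gravity is deliberately *not* removed first: the low-frequency
  gravity projection is the signal of interest.
* angular velocity at **4 Hz** — keeps voluntary movement while attenuating
  higher-frequency content, including parkinsonian rest tremor (4–6 Hz).

Magnitudes of the raw axes come from the unfiltered data; magnitudes of the
filtered families are computed *after* per-axis filtering. The order
matters because the Euclidean norm is nonlinear (a rotating unit gravity
vector has constant magnitude but strongly attenuated filtered axes), and
the filter-then-magnitude order is asserted by test.

Edge handling: reflective (`even`) padding of length 3·(order+1) = 9
samples. Forward–backward filtering leaves a small boundary transient
(≈5·10⁻⁵ relative RMS on a 400 s passband tone); passband idempotence to
<10⁻⁶ holds away from the edges, and tests evaluate it there.

## Features and normalization

Signals are segmented into **1 s windows with 90 % overlap** (50-sample
windows, 5-sample hop at 50 Hz; trailing partial windows are dropped; a
window's timestamp is its start). Each window yields the **mean and sample
standard deviation (n−1)** of sixteen channels — {raw, filtered} × {acc,
gyr} × {x, y, z, magnitude} — i.e. 16 raw + 16 filtered = **32 features**,
independent of the sampling rate.

Each feature v is normalized with the affine map

    v_norm = (2·v − (P5 + P95)) / (P95 − P5),

where P5/P95 are the 5th/95th percentiles (linear interpolation between
order statistics) of the feature over the pooled windows of all subjects
and trials. P5 maps to −1, P95 to +1; values beyond the percentiles exceed
[−1, 1] and are not clipped — the percentile anchors already discount
outliers, and clipping would destroy invertibility. Pooled fitting is the
default reading of an ambiguous protocol sentence; a per-subject scope is
available (`pipeline.fit_cohort_normalization(..., scope="per_subject")`).
A feature with P95 = P5 raises a degenerate-feature error naming it.

## Detection models

Two bagged-tree ensembles (scikit-learn `RandomForestClassifier`; sqrt
feature subsampling, unlimited depth, minimum leaf 1, bootstrap samples of
size n) consume the same normalized windows:

* **Transition model** — positive where ≥50 % of a window lies inside a
  stand-to-sit or sit-to-stand transition; default **35 trees**;
* **Sit model** — positive where ≥50 % of a window is seated; default
  **25 trees**.

All windows not positive for a model's class are its negatives; no class
reweighting is applied by default (an optional `class_weight` passes
through). Ensemble sizes can be re-derived on new data with
`detect.oob_error_curve`, which grows one forest per run and scores the
out-of-bag (OOB) error after every tree from per-tree bootstrap masks
(cumulative majority vote, ties to negative; samples without a vote yet are
excluded). Each training call fits **5 forests** on independent bootstrap
streams and keeps the one with the smallest OOB error.

Cross-validation is **10-fold and subject-grouped by default** (every
subject's trials are held out together, preventing within-subject leakage
through the 90 %-overlapping windows; a trial-grouped option mimics
segment-wise splitting). Normalization percentiles are refit on each fold's
training rows only. All randomness descends from one master seed via
`numpy.random.SeedSequence` with fixed tags per repeat, run and fold.

## From windows to sit phases

Positive windows are expanded to their full 1 s spans and unioned. The
merge stage is gated by *no-Walking segments* — the complement of Walking
intervals within the trial — and applies, in order:

1. detections of the same class separated by **< 1.5 s** (strict) are
   concatenated;
2. Transition detections outside a no-Walking segment are discarded;
3. Sit detections without a Transition detection in the same no-Walking
   segment are discarded (Sit detections are first clipped to no-Walking
   portions, since a sit phase must live inside one);
4. surviving Sit detections in one no-Walking segment are concatenated into
   a single phase spanning the earliest to the latest detection.

A detection straddling a segment boundary belongs to the segment holding
the majority of its duration (ties to the earlier segment) — a declared
choice, as is the emitted phase extent (span of detections, not the whole
segment). The 1.5 s constant was tuned empirically on ambulatory data by
the method's authors and is exposed as a parameter. Walking segments come
from user-provided annotations by default; a clearly-flagged stand-in
detector (windowed mean of the 4 Hz-filtered gyroscope magnitude over a
threshold) makes the pipeline self-contained but is *not* a validated gait
algorithm.

## Evaluation

Window-level **sensitivity** TP/(TP+FN), **specificity** TN/(TN+FP) and
**F1** 2TP/(2TP+FP+FN) are tallied on the same window grid as feature
extraction, scoring prediction and truth by the ≥50 % occupancy rule; since
the basis of published aggregate figures is unstated, event-level recall
(matched events / true events) is reported alongside. Events are matched
greedily, one-to-one, by descending temporal overlap. Segmentation
precision **ΔT = |T_true − T_detected|** contributes one value per start
and per end of each matched event (a per-event mean is optional), and is
summarized by its median plus Tukey-fence outliers (beyond quartiles ±
1.5·IQR — the standard boxplot rule, declared rather than inferred).
Undefined ratios (zero denominators) surface as NaN with a warning, never
as a silent 0.

## Synthetic cohort

The generator states a world in which the pipeline's assumptions hold and
produces (recording, label) pairs with no external data:

* **Scripts** start seated, contain `n_sit_phases` (default 3) sits of
  12–25 s, transitions of 1.5–3 s, and mobility blocks (walking 0.8–1.2 Hz,
  optional 2–6 s quiet standing) that always place a walking bout between
  consecutive sits. The first sit has no preceding stand-to-sit (the trial
  begins already seated), so a script holds n sits, n sit-to-stands and
  n−1 stand-to-sits. Durations are quantized to the sample grid so labeled
  measures equal scripted measures exactly.
* **Signals**: the accelerometer sees the gravity projection of a device
  tilt that moves between 0° (standing) and ~40° (seated) along a cosine
  ramp during transitions; the gyroscope sees the analytic tilt rate (a
  ~30 deg/s pulse) plus a large (~120 deg/s) gait oscillation during
  walking with small counterparts on the accelerometer; optional 4–6 Hz
  tremor (off by default, matching a mildly affected cohort at the ankle);
  white noise (0.02 g, 1 deg/s). Quiet states keep raw acceleration
  magnitude at 1 g.
* **Cohorts** (default 20 subjects × 3/4/5-minute trials) draw gait
  frequency/amplitude, seated tilt and tremor frequency per subject; the
  whole dataset is byte-reproducible from one master seed.

What a green end-to-end test establishes: that the implemented chain —
filters, window statistics, percentile normalization, OOB-selected forests,
subject-grouped CV, merge rules, event metrics — recovers phases whose
boundaries are accurate to well under a second on signals with the stated
phenomenology. What it does not establish: performance on real
parkinsonian gait, chair-specific biomechanics, sensor misorientation, or
walking-detector errors (ground-truth Walking labels gate the merge in
tests). Amplitude choices are plausible values, tunable only through the
declared configuration.

## Numerical choices and limitations

* Strict interval comparisons carry a 1 ns epsilon so grid-aligned gaps of
  exactly 1.5 s never merge through floating-point rounding.
* Forest predictions threshold the tree-vote fraction at >0.5, so exact
  ties go to the negative class; leaves are grown pure, making
  `predict_proba` identical to the vote fraction.
* Half-open `[start, end)` interval semantics throughout; same-label
  overlapping or abutting annotations are merged on read.
* Sit events shorter than the 1 s window are undetectable by construction.
* The boundary bias of the ≥50 % labeling rule (about half a window at each
  phase edge) dominates the ΔT distribution on clean synthetic data
  (median ≈ 0.5 s); no boundary-refinement step is attempted.
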
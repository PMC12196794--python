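# Methods

This note records the modelling choices behind `longlie`: what each
stage assumes, which parameters matter, what the synthetic generator
does and does not emulate, and where the design was genuinely open.

## Coordinate conventions

Keypoints are normalized image coordinates in [0, 1] with the origin at
the top-left and y increasing **downward** (the convention of common
pose estimators). "Above" therefore means smaller y, and the vertical
reference used by the orientation angles is the direction (0, −1). A
keypoint that the estimator failed to localize is *missing* (`None`),
distinct from a keypoint with low confidence, which becomes missing only
after the confidence filter.

## Cleaning

Three rules with three parameters:

| parameter | default | meaning |
|---|---|---|
| confidence threshold | 0.5 | a keypoint is valid only with confidence strictly above this |
| T2 | 3 frames (300 ms) | longest gap bridged by carrying the last observation forward |
| T1 | 10 frames (1 s) | a required keypoint missing longer than this eliminates those frames |

T1 and T2 are not dictated by the data model; the defaults were chosen
so that transient motion blur (a few frames at 10 Hz) is bridged while
sustained occlusion (a second or more) removes frames rather than
inventing poses. Both are configuration-exposed.

Two details matter for reproducibility:

- **Gaps are measured from the last *observed* value**, not the last
  present one: filled keypoints (flagged `filled=True`) never serve as
  sources for further filling. This guarantees every filled coordinate
  is a copy of a real observation and makes filling idempotent.
- **`clean` iterates filter → fill → drop to a fixpoint.** Eliminating a
  run of frames can splice two shorter missing runs of another keypoint
  into one longer than T1; re-running the cycle until nothing changes
  makes the whole operation idempotent (the loop terminates because each
  cycle either removes a frame or changes nothing). The alternative
  order (eliminate before fill) is available as `order="paper"`; the
  default fills first because it strictly reduces data loss.

## Features

The five descriptors are ratios and angles only, hence invariant to
translation and isotropic scale — deliberate, since subject size and
camera distance vary.

- **WHR** uses all available shoulder and knee keypoints (up to 4); at
  least one of each is required. Height extent of zero (exactly
  horizontal shoulder-knee line) is undefined rather than infinite.
- **COGs** are mass-weighted means over a segment's available
  keypoints. Default weights are uniform (centroid). Segment
  membership: upper = nose, shoulders, elbows, wrists; lower = hips,
  knees, ankles; whole = all 13. The angles depend only weakly on the
  weighting; a per-keypoint mass table can be supplied.
- **Orientation angles** are computed as a two-argument-arctangent
  difference between the COG-pair direction and the upward vertical
  through the pair's anatomically lower member, wrapped to (−π, π] and
  folded by absolute value to [0, π]. This is numerically identical
  (to < 1e-9, verified against an arccos-of-dot-product oracle) to the
  angle between vectors, and gives the limits: standing → 0,
  horizontal → π/2.
- **ACB** is the vertex angle at the hip centre between the upper- and
  lower-body COGs, in [0, π]; symmetric in its endpoints; ≈ π for a
  straight body, shrinking as the hip flexes.

Any undefined component (missing inputs, coincident COGs, zero height)
marks the whole frame's features undefined (NaN); windows containing an
undefined frame are dropped with a log entry, never imputed.

z-score normalization statistics are always fit on training data only —
per fold during model selection, on the full training split for the
final model — and reused unchanged at prediction time. Constant features
are rejected by name.

## Windowing

Windows are M = 40 frames (4 s at 10 Hz): long enough to contain a
complete fall from loss of balance to impact, short enough to keep the
classifier causal. Overlap is class-specific — β₁ = 0.75 for falls
(stride 10) and β₂ = 0.50 for ADLs (stride 20) — so the transient fall
dynamics are oversampled relative to abundant steady-state activity.
Window counts follow the standard stride formula
⌊(L − M)/stride⌋ + 1; a closed-form clip count that ignores sequence
length cannot be made consistent with per-sequence footage, so
stride-based segmentation is used throughout. Matrices are flattened
feature-major (all 40 WHR values first) so each feature's temporal
profile is contiguous in the 200-vector.

## Ensemble

Candidates are deliberately lightweight (edge-deployable): KNN (k=5),
RBF-SVC, a single-hidden-layer MLP (100 units, ≤ 500 iterations),
a decision tree, and logistic regression, all at pinned library
defaults. Ranking is by mean F1 over stratified 5-fold CV with ties
broken by precision, then recall, then name; exactly three are refit on
the full training split behind one shared normalization. The SVC
provides probabilities via internal Platt calibration (sigmoid,
3-fold); the other candidates natively; the mechanism is recorded in
the model manifest. Soft voting is the unweighted mean of member
probability vectors; exact argmax ties resolve to the lowest-index
class and are logged. Fall is the positive class for precision, recall,
specificity and AUC (rank statistic over the ensemble fall
probability).

## Long-lie state machine

The monitor consumes per-frame (classification, ACB) pairs. Two
thresholds: time (default 900 s) and orientation change (default 15 %).
Semantics that the pseudocode of such rules typically leaves open, fixed
here:

- The reference orientation is captured at **fall onset** and refreshed
  only on reset — per-frame rebaselining would let arbitrarily large
  cumulative motion pass undetected, so slow drift accumulates.
- The orientation-change check runs on **every** fall-classified frame,
  not only after the time threshold: a repositioning at minute 10 must
  reset the machine (the dual criterion is "fallen ≥ 15 min **and**
  stable throughout"). A nesting that only tests orientation after the
  time threshold would ignore pre-threshold recoveries.
- Comparisons: elapsed ≥ threshold ("at least"); change > 15 % (strict).
- The relative change 100·|θ − θ_ref|/θ_ref is guarded: references below
  ε = 1e-6 rad yield 0 if the new angle is also negligible, else 100.
- Elapsed time is tracked as an integer frame count multiplied by the
  frame period (single rounding), so the alert fires at exactly the
  threshold-crossing frame rather than drifting with accumulated
  floating-point error.

The ACB stream fed to the monitor (`acb_series`) is causally
forward-filled over undefined frames and smoothed with a trailing
5-frame (0.5 s) moving average: the immobility rule compares a scalar
angle across minutes, and single-frame estimator noise (COG composition
changes when a knee drops out for a frame) must not trigger state
resets. Both operations are causal, so the monitor remains streamable.

Crawling or other ambulatory behavior is treated as movement (a reset),
which is a known limitation: a person crawling without managing to get
up is not flagged.

## Synthetic generator

The generator emulates the *statistical* structure the pipeline relies
on, not human biomechanics:

- a two-segment skeleton (trunk + legs hinged at the hip) whose pose is
  (axis inclination, hip flexion, hip-centre position); lateral
  left/right offsets are perpendicular to the segment axes. This drives
  all five features through their documented ranges (upright WHR ≈ 0.31,
  lying ≈ 3.2, ACB ≈ 3.06 rad when lying straight);
- ten subject profiles scaled by the cohort's heights (150–185 cm);
- scripted activities: 32 fall variants (direction × pre-fall activity ×
  speed × end pose), falls easing to horizontal in 0.7–1.4 s (within the
  4-s window bound), pre- and post-fall phases kept under 4 s so every
  fall-labeled window overlaps the transition; 15 ADL scripts (stand,
  walk, sit, deliberate lie-down, crawl, and combinations), where a
  deliberate lie-down eases over 5 s — slower than any fall, which is
  what makes ADL lying separable from post-fall lying at window scale;
- degradation: Gaussian keypoint jitter (sd 0.005 normalized units),
  and per-frame confidence dropout — knees at p = 0.2 (matching their
  ~80 % observed detection rate), other keypoints at p = 0.01. Dropped
  keypoints receive sub-threshold confidence (uniform on [0, 0.5)) so
  the confidence filter, not the generator, removes them.

What it does **not** emulate: occlusion by furniture, view-dependent
foreshortening, estimator bias near image borders, elderly gait, or
correlated multi-keypoint dropout. Classification scores on this
benchmark therefore demonstrate that the pipeline's machinery works and
that the features separate the scripted classes; they do not predict
accuracy on real thermal-camera footage, where class boundaries (slow
falls vs. fast lie-downs) are genuinely harder.

Determinism: every sequence derives its seed from the study seed; stage
seeds in the pipeline derive from one root seed via CRC-salted
`SeedSequence`, so stages can be rerun in isolation.

## Problem sizes

The default study (470 sequences, ≈ 1,800 windows of 200 features) was
sized to exercise every pipeline stage at realistic class balance while
a full run — generation, windowing, 5-fold selection over five
candidates, ensemble fit, evaluation and two 16-minute monitoring
scenarios — completes in a few minutes on one CPU. Long-lie scenarios
use 16 min of footage (≈ 9,800 frames) against the 15-min threshold.

## Known limitations

- The two-segment skeleton cannot represent asymmetric postures
  (kneeling on one leg, reaching) or out-of-plane rotation.
- The monitor assumes one subject; no tracking or identity handling.
- Probability calibration of the ensemble is not assessed beyond the
  rank-based AUC; soft voting averages possibly uncalibrated scores.
- The windowed classifier is trained on sequence-level labels: windows
  from a fall recording that contain only pre-fall activity are still
  labeled "fall". Scripts keep such windows rare (pre-fall phases
  shorter than one window), but the residual label noise is inherent to
  the labeling scheme.
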
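# Methods

## The problem and the data

The package models a binary outcome — perceived neck pain (abnormal,
coded 0) versus no perceived pain (normal, coded 1) — from nine
quantitative predictors measured on a lateral cervical-spine radiograph
and a short questionnaire: gender, age, self-reported daily hours of
social-media use (`h_mean`), two vertebral-curve tangent angles and the
curve–chord enclosed area, and four co-occurrence texture features
(contrast, homogeneity, correlation, energy).  The bundled cohort has 46
subjects (8 normal, 38 abnormal; 19 male, 27 female) and is shipped as a
plain CSV with the per-patient deployed-model score and its implied
class.  The clinical images themselves are not distributable, so every
image-facing stage is exercised on synthetic phantoms with analytic
ground truth.

Validation bounds for the cohort are the printed per-feature minima and
maxima.  Because those are printed at two decimals while some raw values
carry three (e.g. a contrast of 2.881 against a printed maximum of
2.88), bound checks allow half an ulp of the printed precision (0.005).
Round-tripping the cohort through `write_cohort`/`load_cohort` is
value-exact; trailing zeros in the serialised text are normalised.

## Usage bands and usage categories

Two different discretisations of daily hours coexist and are kept
separate deliberately:

* **Descriptive bands** (box-plot grouping): normal subjects form band 1
  regardless of hours; painful subjects are banded by right-closed
  intervals h ≤ 3 → band 2, (3, 6] → 3, (6, 9] → 4, > 9 → 5.  Painful
  subjects reporting ≤ 2 h (which the band vocabulary does not name) are
  folded into band 2 by convention.
* **Rule-set categories**: h ≤ 1 → `1_hours`, (1, 2] → `2_hours`,
  (2, 8) → `2_to_8_10`, ≥ 8 → `8_10_hours`.  This mapping is a declared
  convention; it is validated by the requirement that every cohort
  record satisfies exactly one printed rule, which holds (46/46).

## Image enhancement chain

Steps, in order: full-range window, optional rectangular ROI (the
original workflow's interactive freehand selection is not reproduced —
no interactive UI is in scope, and the phantom fills the ROI), 3×3 mean
smoothing (default 3 iterations), unsharp 3×3 sharpening, Sobel
gradient-magnitude edges, window to the 0–108 gray band, FFT band-pass,
final window, bilinear standardisation to 256×256.  All 3×3 kernels use
edge replication so borders do not darken and bias the co-occurrence
statistics.

The band-pass is a difference of Gaussians in frequency.  A structure of
characteristic size s px concentrates near frequency 1/(2s) cycles/px,
so the low cut uses σ_f = 1/(2·40) and the high cut σ_f = 1/(2·3) by
default.  Optional stripe suppression zeroes a wedge of half-angle
(tolerance % of 90°, default 5 %) around the frequency axis carrying
horizontal or vertical scan lines, never touching the DC term.  The
filter preserves the image mean and is exactly linear before the final
min–max rescale to 8 bits; both properties are tested.  The exact
windowing dialect of any particular desktop tool is not reproduced —
contracts are spectral (amplitude retention in/out of band), not
bit-exact.

## Co-occurrence texture features

Gray levels are quantised into uniform bins over the full [0, 255] range
(never image-adaptive, for determinism across images).  Defaults: one
offset at distance 1, direction 0° (right neighbour), 8 levels,
symmetric accumulation.  The coarse default quantisation is consistent
with the observed feature ranges (homogeneity 0.75–0.98, energy
0.16–0.76).  Energy is the square root of the angular second moment; the
un-rooted sum that some libraries call "energy" is not used.
Correlation is undefined when a marginal variance vanishes and is
returned as a NaN-flagged value so batch extraction never aborts.  With
several offsets configured, features are averaged over offsets
(correlation over the defined ones only).  The implementation is checked
to 1e−12 against an independent double-loop evaluation and against
`skimage.feature.graycoprops` on the quantised raster.

Per-patient texture values of the original cohort are consumed as data;
they are not recomputable because the clinical images are unavailable.

## Curve geometry

Landmarks are inputs (phantom ground truth or JSON); automatic landmark
detection from pixels is out of scope.  The curve is an interpolating
cubic spline (not-a-knot ends) on a chord-length parameter — a composite
C¹ (indeed C²) cubic through all landmarks.  Angles are reported in
[0, 180) against the global horizontal, in upright orientation (image y
is flipped).  The enclosed area closes the densely sampled curve
(200 points per segment, knots always included) with the C1–C7 chord and
takes the absolute shoelace area; a curve crossing its chord sets a
warning flag rather than raising.  Areas are reported both in px² and
calibrated by pixel_size² (default 0.175 mm/px).  The printed cohort
areas are kept exactly as printed; no unit conversion is applied to
them, since their printed unit is not reconcilable with their magnitude.

Accuracy budget, measured on phantoms: mean end-angle recovery error
≈ 0.6° (bound 2°), area error ≈ 0.1 % (bound 10 %).

## Synthetic phantoms and cohorts

The phantom is a single cubic Bezier whose end tangents are set directly
from the requested angles (control handles at one third of the chord),
with `n_vertebrae` Gaussian-profile bright discs at equally spaced
parameters, darker inter-vertebral gaps at the midpoints, optionally
textured background noise (white noise smoothed to a configurable
correlation length), and an optional sinusoidal scan-line stripe.
Intensities are clipped to 8 bits, never wrapped.  Landmarks are the
exact blob centres; the generating curve's chord area is computed from a
dense polygon of the Bezier itself and serves as ground truth.  The
default frame is 512×640 px.  What the phantom does **not** emulate:
anatomical bone shape, cortical/trabecular structure, projection
geometry, scatter, or detector response — so passing tests demonstrate
correct measurement of curve geometry and texture statistics, not
clinical validity on real radiographs.

Synthetic cohorts draw each feature from a class-conditional normal
truncated to the observed cohort bounds, with the overall cohort
mean/SD as the base moments and ±0.45 SD class offsets on angle_1, area
(higher in painful subjects) and contrast (higher in pain-free
subjects), matching the signs of the observed feature–class
correlations.  Hours come from per-class probabilities over the five
usage bands with uniform draws inside a band; band 5 (> 9 h) has zero
default mass because it is unobserved in the study cohort.  A surrogate
model score lands on the correct side of 0.5 except with probability
4/46, emulating the deployed model's error rate.  Truncation more than
6 SD away from the feasible range is rejected.

## Classifiers

**Rule set.**  Evaluation is first-match-wins over the printed order; a
record no rule covers receives the conservative abnormal label with an
explicit flag (such records exist in feature space — a heavy user over
27 with low contrast and a small angle — but not in the cohort).

**Symbolic sigmoid model.**  The printed closed-form expression for the
raw score y is typographically ambiguous, so the resolver evaluates an
enumerated grammar of readings (grouping and division alternatives, a
plain vs nested exponential of contrast, ratio vs power readings of the
small integer constants, with and without a multiplicative gender
factor, plus a deliberately degenerate no-denominator candidate) on all
46 records and selects the parse minimising the maximum |H − H_printed|.
No candidate reproduces the printed classifications — the reference
reading gives y ≈ 1e−5 where ≈ 4.5e−3 would be needed for the printed
H of patient 39 — so the resolver deterministically engages
printed-score mode, in which classification uses the cohort's published
per-patient H values.  The sigmoid constants t₁ = −1797.29 and
t₂ = 7.28, the 0.5 threshold, and the boundary convention (H = 0.5 is
normal) are implemented as published.  An undefined score (non-positive
correlation inside the logarithm, zero denominator) yields the abnormal
label with a flag.

**Cost-sensitive tree.**  A from-scratch C4.5-style inducer: splits
maximise information gain (not gain ratio, matching the stated
criterion), numeric attributes split at midpoints between sorted
distinct values, string attributes split multiway; no pruning (the
published tree is unpruned) and no missing-value handling (the cohort is
complete).  The cost matrix is applied by instance reweighting before
induction: each instance of class i is weighted by its row sum
Σⱼ C(i,j), normalised to keep the total weight equal to n — with the
default [(0,1),(5,0)] over (abnormal, normal) the 8 pain-free subjects
are up-weighted five-fold.  Ties between equal-gain attributes break by
column order; tied leaf labels break toward abnormal (safety-first).
Minimum leaf size defaults to 2.  Trees flatten to IF-THEN rule lists
that replay exactly through the rule machinery (tested as a round trip).

The published tree shape (13 nodes, 7 leaves) and its 94 % test accuracy
arise from an unidentified 66/34 split, so they are not asserted by
retraining; the trainer is validated by properties instead (root split
equals the exhaustive-search optimum, cost reweighting never lowers
minority recall, determinism given dataset order).  The evolutionary
search that produced the symbolic model is likewise out of scope — only
the resulting printed model is deployed.

## Evaluation statistics

The clinical convention takes abnormal as positive (TP = painful subject
detected); the deployed model's published worked example counts the
pain-free class as positive, and the `positive_class` argument covers
both.  Support-weighted averages weight per-class metrics by true-class
counts; support-weighted recall equals accuracy for any binary confusion
matrix (tested as an identity).  Metrics are kept unrounded internally
with a separate display rounding (percent accuracy to integer,
proportions to 2 dp), so published display values are reproducible
without lossy internal rounding.  The published weighted F1 appears
inconsistently as 0.95 and 0.94 in different places; this package
reports the unrounded computed value (0.9426 for the published test
matrix) and leaves the display rounding to the caller.

Standard error is sd/√n with the sample (n−1) SD — the convention that
matches the published per-feature SEs (8.28/√46 ≈ 1.22) — even though
the accompanying text describes sd/n.  Quartiles use linear
interpolation of the empirical CDF; whiskers extend to the most extreme
data within 1.5·IQR of the quartiles; outliers beyond 1.5·IQR are mild,
beyond 3·IQR extreme.  Cross-validation is stratified when every class
can populate each fold and falls back to plain shuffled folds otherwise
(the cohort's 8-member minority cannot stratify 9 folds); fold
assignment is seeded and deterministic.  Feature–class correlations are
offered as both Pearson (point-biserial) and Spearman, reported side by
side — the published correlation table does not state its coefficient or
response coding, so no agreement with it is asserted.

## Problem sizes and determinism

The test suite and the acceptance script use the bundled 46-record
cohort, 20 phantom seeds for geometry recovery, 50 random 8×8 images for
the texture-feature oracle, and 5 noise levels × 10 seeds for the
noise-contrast monotonicity property.  All stochastic stages consume a
single integer seed; identical configuration and seed reproduce every
output byte-for-byte (the pipeline summary excludes artifact paths for
this reason).

## Known limitations

* Printed-score mode means per-patient symbolic scores for *new*
  subjects are only available through the (non-reproducing) best parse;
  the resolver reports its residual so callers can judge.
* The published overall mean/SD for daily hours (2.04/1.40) is not
  reproducible from the bundled hours column (4.95/2.94) and may
  summarise band indices; the fixture keeps hours as printed and no
  reconciliation is attempted.
* Phantoms are geometric/textural stand-ins, not anatomically realistic
  renderings; no DICOM I/O.
* No significance-testing suite beyond descriptives and correlations.
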
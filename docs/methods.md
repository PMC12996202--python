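# Methods

`poseactivity` quantifies the motor activity of a seated child from a
33-keypoint pose-landmark time series and asks two questions: do regional
movement indices differ between a hyperactivity-risk group and a
comparison group, and can the two groups be classified from those
indices?  Because raw recordings of children are typically not shareable,
the package ships a synthetic cohort generator with the same statistical
structure, so every stage is testable end to end.

## Input model

A session is a `(T, 33, 3)` array of normalized image coordinates plus a
`(T, 33)` confidence matrix, at 30 fps, trimmed to 180 s (5,400 frames).
The landmark layout is the standard full-body convention: face 0–10,
shoulders 11/12, elbows 13/14, wrists 15/16, hand landmarks 17–22, hips
23/24, knees 25/26, ankles 27/28, heels 29/30, foot-index 31/32.  The
depth (z) channel of monocular pose estimation is relative and noisy; it
is carried through the types but never enters a movement index.

## Quality control

Order is fixed: confidence gating → exclusion decision → gap repair →
smoothing.

* **Gating.** A (landmark, frame) cell is invalid when confidence < 0.50
  (strict: a cell at exactly 0.50 is valid).
* **Exclusion.** A session is dropped when global missingness exceeds
  20 %.  Missingness is the fraction of invalid cells over all
  33 × T cells; a frames-with-any-invalid-landmark variant is available
  in `QcConfig` for sensitivity analyses but is pathologically strict
  with 33 landmarks and is not the default.
* **Gap repair.** A gap is a maximal invalid run for one landmark.
  Interior gaps of ≤ 10 frames (≤ 333 ms) are filled by per-axis linear
  interpolation between the flanking valid samples — exact for affine
  motion.  Longer interior gaps use a constant-velocity Kalman filter
  (1-D position+velocity state per axis; process noise 1e-4, measurement
  noise 1e-2 in normalized-unit terms, both exposed in `QcConfig`): the
  filter state is estimated on the valid run before the gap and, reversed
  in time, on the run after it, and the two extrapolations are blended
  with a linear cross-fade so the fill meets both endpoints.  A
  forward-only variant is available (`kalman_two_sided=False`).
  Boundary gaps hold the nearest valid value, since one interpolation
  endpoint does not exist.  Valid samples are never modified.
* **Smoothing.** Each repaired trajectory is passed through a causal One
  Euro filter (adaptive cutoff `f_c = min_cutoff + beta * |dx̂|`, with
  the derivative pre-smoothed at `dcutoff`); defaults are the filter's
  reference parameters, min_cutoff 1 Hz, beta 0.007, dcutoff 1 Hz.  The
  update is written in incremental form (`x̂ += a (x − x̂)`) so a constant
  signal is passed through bit-exactly.  Smoothing is applied after gap
  filling; the filter requires a complete signal, and this order keeps
  the repair anchored to raw valid samples.

## Movement indices

The 33 landmarks collapse to 17 analysis points: head = centroid of the
11 facial landmarks, per side: shoulder, elbow, wrist, hand (centroid of
thumb/index/pinky), hip, knee, ankle, foot (centroid of heel/foot-index).
All points are expressed in the pelvis-root frame, i.e. relative to the
per-frame midpoint of the two hip landmarks, removing whole-body
translation.  Implementation note: landmarks are centered before
aggregation — algebraically identical to centering the composites, but
exactly translation-invariant in floating point.

A regional activity index is a cumulative windowed displacement:
positions are averaged in consecutive non-overlapping 5-frame windows
(~167 ms), Euclidean displacement is computed between successive window
means in the x–y plane only, and summed over the recording.  With 5,400
frames there are 1,080 windows and 1,079 displacements; a constant
velocity of v units/frame therefore yields an index of exactly 5,395 v,
which serves as a closed-form oracle.  Windowing suppresses frame-level
jitter relative to frame-to-frame summation.  A trailing remainder of
frames (T not divisible by 5) is dropped; at the protocol length there is
none.  The global activity index is the exact sum of all 17 regional
indices — the hip indices are included in that sum ("all regions") even
though they are near-degenerate under root-centering.

Indices are translation-invariant (pelvis-root property) and scale
equivariant (multiplying coordinates by c multiplies every index by c);
both are enforced by tests, the former bit-exactly on dyadic-grid data.

## Statistics

Per movement outcome (17 regions + global), Shapiro–Wilk in each group
gates the test family; the movement indices are heavily right-skewed, so
the nonparametric branch is the operative one.  Group comparisons use
Mann–Whitney U with midranks, reported as min(U₁, U₂), a tie-corrected
standardized statistic Z = (U − n₁n₂/2)/σ_U, a two-sided normal p value
(no continuity correction), and effect size r = |Z|/√N.  Direction is
taken from mean ranks and suppressed (n.s.) when p ≥ 0.05.

Across the 15 tabulated regions (hips excluded as near-degenerate),
Benjamini–Hochberg step-up adjustment controls the FDR.  A sensitivity
analysis groups all 17 regions into five a-priori anatomical domains
(head alone; each limb's shoulder/hip-to-distal chain of four) and
applies Bonferroni within domain: α_adj = 0.05/m, hence 0.0125 for each
limb domain and 0.05 for the single-outcome head domain, with strict
inequality for significance.

Associations with the teacher hyperactivity rating use Spearman's ρ
(midranks), a t-approximation p value (n − 2 df), and a Fisher-z interval
with SE = 1/√(n−3); these exploratory correlations are deliberately not
multiplicity-corrected.  Demographics use a pooled-variance two-sample t
test from summary statistics and a Pearson χ² without continuity
correction.  Classification proportions carry Wilson score intervals and
pooled AUCs carry Hanley–McNeil normal-approximation intervals
(Q₁ = A/(2−A), Q₂ = 2A²/(1+A)).

## Classification

Fifteen regional indices (no hips, no global index — the latter is a
linear combination of the features and would leak redundancy) feed five
families: SVM, random forest, extremely randomized trees, AdaBoost over
depth-limited trees, and kNN.  Nested stratified 5-fold cross-validation
separates hyperparameter selection (inner loop, grid search scored by
ROC-AUC by default) from evaluation (outer loop); every participant is
scored exactly once out of fold.  The inner search is a direct loop over
the grid rather than a search wrapper, keeping per-fit overhead
negligible at n ≈ 50; ties resolve to the earliest grid point, which
makes selection deterministic under a fixed seed.

Default grids (a design choice, not a claim about any particular study):
SVM — kernel {rbf, linear}, C {0.1, 1, 10, 100}, γ {scale, 0.01, 0.1, 1};
forest/extra-trees — 100/300 trees, depth {∞, 3, 5}; AdaBoost — 50/200
estimators, learning rate {0.1, 1.0}, stump depth {1, 2}; kNN —
k {3, 5, 7, 9}, vote weighting {uniform, distance}.  SVM and kNN are
z-scaled inside the CV pipeline (scaler fit on the training fold only);
tree ensembles are left unscaled.  SVM and the tree ensembles use
inverse-frequency ("balanced") class weights; kNN has no weight
parameter, so its imbalance handling is realized through the
distance-weighted voting option in its grid.

Metrics come from the pooled out-of-fold confusion matrix with risk as
the positive class.  Every Wilson interval — including sensitivity and
specificity, whose natural denominators are subgroups — uses the whole
cohort n as the denominator.  This is statistically unconventional but is
the reporting convention this package reproduces; it is implemented in
one place (`compute_metrics`) and documented here.  AUC is summarized two
ways on purpose: the mean ± sd of fold-wise AUCs, and the pooled
out-of-fold AUC with its Hanley–McNeil interval; because AUC is a
nonlinear rank statistic the two differ, and folds containing one class
are excluded from the fold-wise mean with a warning.

Permutation feature importance is computed on each held-out fold for the
inner-loop winner: baseline accuracy minus mean accuracy after shuffling
one feature (20 seeded repeats, averaged over folds).  An identity
permutation yields exactly zero importance, which is used as a degenerate
test.  A demographic baseline (age + sex, SVM, same nested scheme)
quantifies how much performance basic demographics alone could explain.

## Synthetic cohort generator

The generator is a phenomenological stand-in for seated-child
recordings, not a biomechanical model.  Per segment and side, a planar
displacement follows a discrete Ornstein–Uhlenbeck process
`d_t = (1−θ) d_{t−1} + σ ε_t` around a fixed seated base pose
(θ = 0.05/frame), which produces bounded, fidget-like motion.
Kinematic-chain coherence: elbow inherits 0.6 of shoulder displacement,
wrist 0.7 of elbow, hand 0.9 of wrist; knee 0.5 of hip, ankle 0.7 of
knee, foot 0.9 of ankle; the 11 facial landmarks move rigidly with one
head process.  Control-arm per-frame noise scales (normalized units):
head 1.0e-3, shoulder 5e-4, elbow 8e-4, wrist 1.2e-3, hand 1.5e-3,
hip 2e-4, knee 8e-4, ankle 1.2e-3, foot 1.5e-3.  Risk-arm multipliers
concentrate the group difference distally: wrist/hand/ankle/foot × 2.0,
elbow/knee × 1.5, head × 1.4, shoulder × 1.1, hip × 1.0.  Each child
carries a lognormal(0, 0.35) activity factor multiplying all segment
scales; independent Gaussian jitter (sd 5e-4) is added per landmark and
frame; z receives small group-independent motion.  Confidence is 1.0
outside dropout bursts; bursts arrive at 0.3 per landmark per minute
with geometric lengths (p = 0.15, mean ≈ 6.7 frames, so some exceed the
10-frame linear-repair limit and exercise the Kalman path), and inside a
burst confidence is uniform on [0, 0.5) — the pipeline only ever uses
the 0.5 threshold, so finer confidence structure would be untestable.

The teacher (Conners) hyperactivity score is
`round(clip(−7.8 + 8.8 · latent + noise, 0, 30))` with latent = the
child's activity factor times the arm's mean distal multiplier and noise
sd 2.0, chosen so the control arm sits near mean 1.5 / median 0 and the
risk arm near mean 11, with rating positively coupled to realized
movement.  Ages are uniform on 48–60 months; sex is drawn per arm at
boy proportions 14/20 (risk) and 15/31 (control), both configurable.

No distributional facts about real raw trajectories are available to
calibrate against, so these defaults are fixed once for qualitative
fidelity.  What passing tests on this generator demonstrate is that the
pipeline recovers the structure the generator puts in (distal-dominant
group differences, rating–movement coupling, movement features beating
demographics); they say nothing about pose-estimator failure modes
beyond confidence dropouts and i.i.d. jitter, camera motion, occlusion
structure, or true child biomechanics.

## Problem sizes used by the test and acceptance runs

Simulation-based checks run at reduced session lengths, a deliberate
design choice: movement indices are sums over windows, so a shorter
session is the same estimator at smaller T.  Null-calibration cohorts
use 10 s sessions (500 cohorts in the test suite, 150 in the acceptance
script); effect-recovery cohorts use 15 s sessions (100 and 24
respectively); the acceptance script additionally analyzes one cohort at
the full geometry (20 risk / 31 control, 180 s, 30 fps).  The null
calibration band (raw-p rejection rate in [0.03, 0.07] at α = 0.05 over
2,000 tests) allows for binomial noise, the normal approximation at
n = 20/31, and dependence between features of the same cohort.

## Known limitations

* The generator's OU-plus-inheritance motion model is not a claim about
  child movement; only its ordinal structure (distal > proximal risk
  amplification) mirrors the study conditions.
* Kalman gap repair assumes locally constant velocity; fast direction
  changes inside a long gap are smoothed over.
* The whole-cohort Wilson denominator makes subgroup-metric intervals
  narrower than subgroup-denominator intervals; it is kept for fidelity
  to the reporting convention being reproduced.
* Angular kinematics, limb-length normalization and velocity spectra are
  out of scope.
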
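# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the `handsyn` pipeline, in the order the stages run.

## Synthetic data generator

The generator (`handsyn.synthdata`) provides the three data modalities the
pipeline consumes, with the generative structure the downstream analyses
assume.  It is first-class, tested code, not a test fixture.

**Postures.**  A posture set is `mean + W·L + ε`: a random mean posture
(per-joint angles ~ N(30°, 12°)), latent weights `W` (20 postures ×
`n_latent`) with orthogonal, exactly variance-scaled columns, an
orthonormal latent basis `L` (QR of a seeded Gaussian matrix), and i.i.d.
Gaussian repetition noise ε.  Defaults: 20 postures × 5 repetitions × 24
joints; 3 latent synergies with variance fractions (0.5, 0.3, 0.1) of a
total across-posture variance of 400 deg²; repetition noise 2.89° per
joint, sized so that after averaging 5 repetitions the residual noise is
roughly the remaining 10% of total variance.  This is the regime in which
the first three principal components of real grasping data explain more
than 80% of postural variance.  Because the latent weight columns are
orthogonalized and scaled exactly, the noiseless data's total variance
equals the sum of the component variances to machine precision — a tested
invariant.

**EMG.**  Per trial and channel, a Gaussian carrier band-passed to
30–450 Hz at 2 kHz is scaled by a channel-specific affine function of the
posture's latent muscle weights (rectified at 5% of baseline) plus
additive broadband noise.  Defaults: 5 channels, 6 repetitions, 5000 raw
samples (2.5 s), modulation depth 0.5 of baseline, additive noise 0.05.
The raw trial length is chosen so the analysis window after resampling to
1 kHz is 2500 samples.  The carrier emulates a surface-EMG-like spectrum
within the analysis band; it does not model motor-unit physiology,
electrode placement or movement artifacts.

**Voxel patterns.**  `response(v, p) = Σ_k coef(v, k) · weight(p, k) +
activation(v) + noise(v, p)`.  Coefficient maps are Gaussian random
fields on the integer grid smoothed to `smoothness_fwhm` (default 4
voxels, reflect boundary) and globally rescaled per component so an
informative voxel's signal has unit standard deviation across postures
regardless of the scale of the supplied weights.  A configurable fraction
of voxels (default 0.5) carries zero coefficients; this uninformative
region is defined by thresholding a second smoothed field, so informative
voxels form contiguous blobs as in real activation maps.  Informative
voxels also receive a constant positive offset (default 1.0), emulating
the above-rest mean of t-score responses — this is what makes mean-response
voxel selection and the ROI t-test meaningful.  Response noise is
spatially smooth (default FWHM 2 voxels, matching 4 mm smoothing at 2 mm
voxels) but temporally white across postures; no physiological noise
structure is modeled.  Defaults: 20×20×20 grid (8000 voxels), noise SD
0.5 (signal-to-noise 2:1 on informative voxels).

What passing tests on these data do *not* show: robustness to
biomechanically correlated joint noise, to EMG cross-talk, or to the
spatially heterogeneous, temporally autocorrelated noise of real BOLD
data.  The generator supports the structural and calibration claims of
the procedures, not empirical effect sizes.

All streams derive from a single seed through fixed CRC-keyed
sub-sequences, so identical configurations give bit-identical outputs
across processes.

## Kinematic models

Repetitions are averaged per posture; the 20×24 matrix is centered by the
grand-mean posture; PCA is computed by SVD of the centered matrix (more
stable than covariance eigendecomposition at 20×24).  Loadings are
unit-norm rows ordered by singular value; since PCA signs are arbitrary,
each loading is flipped so its largest-magnitude entry is positive,
making models deterministic.  New data are projected as
`(X − mean)·Lᵀ` — the stored transformation includes the training mean.
The individual-digit model sums joint angles within each digit
(`mode="mean"` averages instead; summation is the default operational
definition).  The default 24-DoF labeling (thumb 6 DoF including CMC
rotation; index/middle 4; ring/little 5 including a CMC arch flexion) is
a documented convention and fully configurable; all computations depend
only on the joint→digit map, not on the labels.

## EMG model

Trials are resampled to 1 kHz (polyphase), band-pass filtered with a
4th-order zero-phase Butterworth and notch-filtered at 50 Hz (Q = 30).
The nominal 30–1000 Hz band is not realizable at a 1 kHz output rate, so
the low-pass edge is capped at 0.99 × Nyquist = 495 Hz.

The per-channel feature vector has 82 entries: 22 primary time-domain
features on the full 2500-sample window (MAV, RMS, variance, SD, waveform
length, zero crossings, slope-sign changes, Willison amplitude, iEMG,
SSI, log detector, DAMV, DASDV, myopulse rate, maximum fractal length,
peak, skewness, kurtosis, and 4 least-squares AR coefficients) plus the
median, MAD, skewness and kurtosis of the 15 amplitude-type features
tracked over 250-sample windows with 50% overlap (15 × 4 = 60).  The
composition is registry-driven and configurable; each registry entry
declares its amplitude-scaling class (linear, quadratic, invariant,
other), which the tests assert.  Thresholded features use fixed absolute
thresholds (Willison 0.05, myopulse 0.016 in input units); zero-crossing
and slope-sign counts use a zero threshold and are therefore scale
invariant.  Degenerate inputs (zero or constant signals) yield defined
zeros rather than NaNs.

Features are z-scored per column before PCA (they span many orders of
magnitude; scaling is configurable off), PCA runs across all trials, and
the five component scores are averaged across the six repetitions of each
movement — PCA first, then averaging, which a regression test pins down
against a hand-computed case.

## Rank-accuracy validation

One fold per (posture, repetition): the left-out repetition is the probe;
the same repetition index is left out for every posture and the remaining
repetitions are averaged, so every test item aggregates equally many
trials and all items are exchangeable under the null — this makes chance
exactly 50% for any number of gestures, which the permutation and
simulation tests confirm.  PCA (k components) is fitted to the test set;
the probe is transformed with the fitted parameters; Euclidean distances
in component space are ranked with ties broken by average rank (ties have
probability zero on continuous data but must be defined); rank r of n
maps to `100·(n−r)/(n−1)`.  Scores average across repetitions, then
postures.

The permutation null shuffles test-set labels independently in every fold
of every iteration.  Distances do not depend on labels, so a shuffled
fold scores the rank percentage of a uniformly drawn test item; the
implementation samples those ranks directly, which is exactly equivalent
and makes the printed 10,000 iterations essentially free.  The p-value
uses the (r+1)/(n+1) estimator, so p ≥ 1/(n_iter+1).  The statistic
entering the permutation comparison is the mean accuracy (per-gesture
accuracies are also reported).

## Encoding procedure

190 leave-two-out folds (all unordered pairs of 20 stimuli).  Per fold:

1. **Stage-1 selection** — top 5000 voxels by mean training response,
   ties broken by voxel index.
2. **Training** — per-voxel OLS of the 18 training patterns on the five
   synergy weights.  An intercept is included by default (patterns are
   t-scores with a nonzero baseline; configurable off).
3. **Stage-2 selection** — top 1000 voxels by training R².
4. **Cluster pruning** — connected components among the selected voxels
   under face adjacency (6-connectivity, the conservative reading of
   "nearest neighbor"; 18/26 available); components under 50 voxels are
   dropped.  If nothing survives, the fold decodes within the unpruned
   stage-2 set and a warning is logged, rather than forfeiting the fold —
   forfeits would bias the chance level downward on data without large
   clusters.
5. **Pairwise decoding** — the two held-out patterns are predicted from
   their weights and each prediction is assigned to the observed pattern
   with the smaller correlation distance (1 − Pearson r); zero-variance
   patterns take the maximal distance 2.  Correct count per fold is 0, 1
   or 2; chance is 50%.

Stage counts auto-clamp (logged) to the available voxel count so the same
code runs on desk-scale grids.  Overall accuracy is the percentage of the
380 held-out patterns assigned correctly.  A voxel's recruitment score
increments by the fold's number of correctly predicted patterns whenever
the voxel is in the final set — 0 to 380; the per-pattern (not per-fold)
increment is what makes 380 the attainable maximum.

The permutation null re-runs every fold with the 18 training weights
shuffled independently within each column — implemented as a
without-replacement column permutation, which preserves each column's
variance exactly (an independent with-replacement draw is available).
The held-out pair and its weights are never touched.  Group-level maps
binarize per-subject recruitment maps, sum them, and threshold at a
minimum subject count (default 4, i.e. more than a third of nine
subjects).

## Representational analyses

The ROI is defined by a per-voxel one-sample t-test of the mean response
against rest, Benjamini–Hochberg corrected (q = 0.05).  ROI patterns are
globally z-scored, reduced to five PCs, and converted to 20×20 Euclidean
representational similarity (RS) matrices; model RS matrices are computed
from the 20×5 model weight tables.  Second-order comparisons are Pearson
correlations over the 190-element off-diagonal upper triangle (standard
RSA practice).  The Mantel test permutes one matrix's stimulus labels
(simultaneous row/column permutation, 10,000 iterations) — equivalent
under the null to permuting both.  The noise ceiling's upper bound
correlates each subject's RS with the group mean including that subject;
the lower bound uses the leave-one-subject-out mean.

MDS minimizes metric stress by SMACOF majorization (seeded random
initialization, relative tolerance 1e−9, 500 iterations); the in-package
implementation exposes the per-iteration stress trace so the monotone
nonincrease guaranteed by majorization is testable, and its final stress
is cross-checked against scikit-learn's `smacof` in the tests.  Procrustes
alignment (translation, rotation, uniform scale) comes from scipy.

Per-synergy voxel fits are squared Pearson correlations between a voxel's
20 responses and one synergy's weight vector (zero-variance voxels get
R² = 0, logged).  The topography index C is the Pearson correlation
between pairwise standardized Euclidean distances (each dimension divided
by its across-item SD) in voxel-coordinate space and in synergy-fit
space.  Its permutation test has two modes: *voxel-shuffle* permutes
feature rows across voxels (applicable to a single map), and
*subject-shuffle* rebuilds the group feature space after randomly
permuting each subject's synergy columns (random subject combinations;
requires per-subject maps).  The exact combinatorial scheme of the
group-averaging null is not uniquely determined by its verbal
description; both modes are exposed and the choice is recorded in
results.

Cross-subject synergy stability uses cannot-link-constrained k-means:
each subject's synergy weight vectors (sign-aligned to a reference
subject first, since per-subject PCA signs are arbitrary) must land in
distinct classes.  The assignment step solves an exact minimum-cost
matching per subject (Hungarian algorithm), which enforces the
constraints and yields exactly `n_subjects` members per class; centroid
updates then make the objective monotone nonincreasing.  The full
metric-learning variant of MPCK-Means is not implemented — the clustering
is used only to establish cross-subject correspondence, for which the
fixed Euclidean metric suffices.

## Decoding

ROI voxel patterns are z-scored and reduced to five PCs.  A
leave-one-stimulus-out loop fits 24 independent per-joint OLS regressions
(5 predictors + intercept) on 19 stimuli and predicts the held-out row,
assembling the 20×24 reconstruction.  The plain reading of "multiple
linear regression" is per-response OLS; a reduced-rank variant that
predicts synergy weights first and expands through the loadings is
provided as an option.  Fidelity: subject-wise R² is the squared Pearson
correlation of the vectorized matrices; posture-wise R² per row; rank
accuracy ranks each reconstructed row against the 20 originals, with a
10,000-iteration label-permutation null.  Wrist angles are outside the
24-DoF posture representation throughout.

## Problem sizes and numerical choices

Default end-to-end runs use the study-design sizes: 20 postures × 5
repetitions, 8000-voxel grid, 190 folds, 10,000-iteration
rank/Mantel/topography permutations, 1000-iteration encoding null (off by
default in `report`; enable with `run_encoding_null: true` — it re-runs
all 190 folds per iteration and dominates the runtime at roughly a second
per iteration).  Everything else completes in well under a minute per
stage on one CPU.  Tests exercise the same code on smaller grids
(8³–10³) with proportionally reduced selection thresholds.

Tolerances: orthogonality and variance identities are asserted at 1e−8 to
1e−12; Monte-Carlo calibration checks use tolerances of 1–2 percentage
points at the replicate counts stated in each test.  Degenerate inputs
(constant signals, zero-variance voxels or patterns, rank-deficient
designs, infeasible constraints) raise explicit errors or take defined
fallbacks as described above.

## Known limitations

- The EMG feature registry is a documented convention; any specific
  published 82-feature list can be substituted via the registry.
- The generator's noise models are Gaussian and stationary; empirical
  accuracies obtained on synthetic data characterize the procedures, not
  any particular experiment.
- The topography subject-shuffle null and the group-averaging scheme it
  permutes admit multiple formalizations (see above).
- MDS finds a local stress minimum per seeded initialization; use
  multiple seeds for publication-grade embeddings.
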
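# Methods

This note documents the models, numerical choices, and known limitations of
`taskcpca`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Constrained PCA of task-related variance

The analysis separates BOLD variance into a task-predicted part and a
residual by multivariate regression of the stacked, nuisance-cleaned data
`Z` (scans × voxels) on the stacked FIR design `G`, then decomposes only
the predicted part:

    C = (GᵀG)⁻¹GᵀZ,   G C = U D Vᵀ

Numerically the fit uses a thin QR of `G` (`G = QR`) and takes the SVD of
`R C`; since rank(GC) ≤ #design columns this is exact and far cheaper than
an SVD of the full predicted matrix. A rank-deficient design falls back to
the pseudo-inverse with a condition-number warning.

**Loadings and scaling.** Component loadings are `V D` (singular-value
scaled), so "dominant loadings" thresholds refer to these scaled values.
Unrotated variance fractions are `D²/ΣD²` over the full task-related
trace; after rotation, each retained component's task-variance fraction is
its column sum of squared rotated loadings over the same trace (rotation
redistributes but conserves their total).

**Sign convention.** Each component is oriented so its maximum-absolute
loading is positive; deactivation (e.g., default-mode) then appears as a
negative-going predictor-weight time course rather than being discarded.

**Varimax.** The standard SVD-update algorithm, converged when the
relative criterion gain falls below 1e-10 (cap 1000 iterations, warning on
non-convergence). Kaiser row-normalization is available but **off by
default**: with thousands of voxels of which only a few percent carry
signal, normalizing every voxel row to unit communality gives pure-noise
voxels the same rotational weight as network voxels and measurably degrades
separation; spatial maps are therefore rotated on the singular-value-scaled
loadings directly.

**Component count.** The scree operation suggests a count by the chord
heuristic (the point of the singular-value curve farthest below the line
joining its first and last values; components before that elbow are
retained). The suggestion is advisory — the fitted count is a config
choice, defaulting to 4 here.

**Predictor weights.** Rotated score columns are regressed onto the
block-diagonal `G`; with the block structure each coefficient belongs to
one (subject, condition, poststimulus bin), tracing that subject's
estimated HDR for that condition. Counter-rotation of the scores keeps
`scores · loadingsᵀ` invariant under rotation.

**Subject expression maps.** For group inference a per-subject spatial map
of network engagement is needed. The map is the per-voxel regression slope
of the subject's residualized data on a *common* reference time course:
the cohort-average predictor weights applied to the subject's own FIR
design. The common shape is essential — regressing on the subject's own
score segment cancels the subject's amplitude (the slope of `a·x` on `a·x`
is 1 regardless of `a`) and would erase exactly the group differences the
test is after. This is the dual-regression convention adapted to CPCA; the
per-subject beta map within the mask is the selectable alternative.

## Design and preprocessing conventions

- **Onset-to-scan mapping**: a trial is assigned to the first full scan at
  or after its onset; no fractional-scan interpolation. FIR windows
  running off the scan axis are truncated with a warning.
- **Bin time labels**: bin *k* is labeled (k − 0.5)·TR (scan midpoint) by
  default — for TR 3.25 s: 1.6, 4.9, 8.1, 11.4, 14.6, 17.9 s — with a
  scan-onset convention (0, 3.25, …) selectable. Only labels change, never
  the fitted values.
- **Nuisance ordering**: motion columns first, then Legendre drift, then
  intercept; removal by a single least-squares projection (the projection
  is onto the joint span, so the listed order documents intent rather than
  changing the result).
- **Standardization before stacking**: each subject is demeaned per voxel
  and divided by one scalar, the subject's **median voxel SD**. The median
  is a noise-scale estimate that ignores the few strongly active voxels,
  so between-group amplitude differences survive standardization. Per-voxel
  z-scoring is selectable but not default: because a voxel's SD contains
  its signal, it nonlinearly compresses high-amplitude voxels and distorts
  loading maps.
- **Design centering**: each subject's FIR columns are demeaned over that
  subject's rows (an implicit per-subject intercept). Without it, the
  demeaned data are regressed on un-demeaned indicators and the baseline
  leaks a non-constant bias into every FIR coefficient; with it, noiseless
  recovery of planted bin amplitudes is exact. Block-diagonality is
  preserved.

## Mixed ANOVA

A two-within (Time × Force), one-between (Group) design on per-subject
predictor-weight cell means, via the classical sums-of-squares
decomposition with subjects as a random factor nested in group; group
sizes may differ (17 vs 24 here), each within effect is tested against its
own subject-interaction error term. Partial η² is
SS_effect/(SS_effect + SS_error-of-that-effect). Greenhouse–Geisser ε is
computed per within effect from the pooled within-group covariance of
orthonormal contrast scores (double-centering formula for the plain
covariance entry point), and both uncorrected and GG-adjusted p values are
always reported, making the sphericity check explicit output. Missing
cells raise — no silent imputation. Simple main effects are per-bin paired
(Force) or pooled-variance two-sample (Group) t tests; the FDR family is
the six poststimulus bins of one follow-up, adjusted by Benjamini–Hochberg
(statsmodels implementation behind the module surface).

## Permutation inference and TFCE

The group statistic is the voxelwise pooled-variance two-sample t on the
expression maps, restricted to the network's extreme-fraction mask. TFCE
integrates cluster extent^E × height^H over thresholds (defaults H = 2,
E = 0.5, 26-connectivity, step = max/100 — the standard published
parameterization; the paper-scale default of 5000 permutations is config).
Positive and negative tails are enhanced separately and inference is
directional, mirroring the two directional group contrasts. The null is
the distribution of the maximum enhanced statistic over the mask under
group-label permutation. Conventions: when all distinct labelings number
no more than the requested permutations they are enumerated exhaustively
and the null is exactly that set (identity labeling included), giving
p = #{null ≥ obs}/N; under random sampling the identity is added
explicitly, p = (1 + #{null ≥ obs})/(1 + n), so p > 0 always.

## Behavioral composite

PCA on the correlation matrix (z-scored measures) of grip strength, NHPT,
and BBT percentages; PC1 is the composite. Orientation is fixed so that a
**higher composite means better motor performance** (PC1 is aligned with
the mean of the standardized performance measures) and is reported with
the scores, because the sign of a principal component is otherwise
arbitrary and silent sign flips would invert every downstream correlation.
Brain–behavior association is a Pearson correlation with a two-sided p.

## The synthetic cohort

The generator emulates the emulated study's design: 24 controls + 17
patients, 50 grips per subject at 10%/30% MVC in randomized balanced
order, 3 s grips, ISI ~ U(3, 7) s, TR = 3.25 s, run length derived from
the schedule plus a full FIR tail (~130 scans). Four planted networks
differ in both spatial pattern (Gaussian blobs on a 12³ grid; left
hemisphere = low x) and FIR bin curves — an early attentional transient, a
sustained visual response, a mid-latency motor peak with undershoot, and a
late default-mode deactivation. Distinct HDR timing is what makes the
networks identifiable to the method; equal-shaped curves would collapse
the evoked data to (temporal) rank 2. Network strengths form a realistic
strongest-to-weakest hierarchy, so recovered task-variance fractions span
roughly 19% down to 5%.

Group structure: patients express the motor network at 0.6× and the
default-mode deactivation at 0.5×; per-subject amplitudes carry lognormal
jitter (σ = 0.25). Noise is AR(1) (φ = 0.3) with innovation SD scaled to a
marginal SD of 0.35 signal units — peak single-scan SNR ≈ 2–3 in network
cores, a deliberate desk-scale choice. Quadratic Legendre drift and
random-walk motion traces are added and regressed back out by the
pipeline. Patients' three behavioral measures load 0.9 each on the planted
motor amplitude (coupling 100 %-points per amplitude unit, noise SD 10),
clipped at zero. Lesions are small deep left-hemisphere blobs below the
cortical network blobs, emulating subcortical stroke and keeping
lesion–network Dice small.

What the generator does **not** emulate: spatial autocorrelation of fMRI
noise, physiological (cardiac/respiratory) structure, susceptibility
artifacts, motion-correlated signal, registration error, or hemispheric
asymmetry of noise. Passing recovery tests therefore demonstrates the
estimator chain is correct and calibrated under the declared generative
model, not that real-data effect sizes will match.

## Reduced problem sizes

Calibration studies use sizes chosen for desk-scale runs: ANOVA type-I
calibration uses 1000 null datasets of the full 41-subject 6×2×2 design;
FWE calibration uses 500 null datasets with a 200-permutation scheme on a
5³ mask with 6 + 6 subjects and a 20-step TFCE integration; network
recovery uses 10 fresh cohorts at the default 12³ volume. The acceptance
script mirrors these sizes and records each `n` alongside the value.

## Known limitations

- Only orthogonal (varimax) rotation; no oblique variants.
- The permutation test supports two-group label exchange only (no
  exchangeability blocks, no sign-flip one-sample design, no variance
  smoothing).
- The ANOVA decomposition is the classical weighted-means one; with the
  only imbalance being group size and complete within-subject cells it is
  exact under the null (verified by simulation), but it is not a general
  Type-III machinery for arbitrary missingness.
- Tie-breaking in extreme-fraction masks is by voxel index order, which is
  deterministic but arbitrary under exact ties.
- The CPCA variance partition attributes to "task" anything correlated
  with the FIR design within subject; slow drifts surviving nuisance
  regression can leak in.
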
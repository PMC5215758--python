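# Methods

## Model and procedure

The pipeline treats a face as two coupled data blocks measured on the same
specimen: a landmark configuration (shape) and a photograph (texture).

**Generalized Procrustes analysis.** Configurations are centered, scaled to
unit centroid size (the square root of summed squared distances from the
centroid), and iteratively rotated to the evolving mean; the mean is
recomputed as the renormalized average each iteration until its RMS
displacement falls below 1e-10 (at most 100 iterations; non-convergence is
flagged on the result, not raised).  Rotations are proper (det +1) — faces
have handedness, so reflections are never allowed.  Procrustes distance is
reported as the Euclidean norm of the coordinate difference, the
tangent-space approximation appropriate for the small shape variation of
within-population face samples.

**Sliding semilandmarks.** Points digitized on curves have no exact
anatomical identity along the curve; they are relaxed by sliding along the
local tangent (central differences of curve neighbors, one-sided at ends —
curve endpoints are fixed) so as to minimize the TPS bending energy of the
residual against the sample mean.  For each specimen the tangent offsets have
a closed-form generalized-least-squares solution.  The implementation fixes
the alignment, the mean's bending-energy matrix, and then alternates two
exact minimizers of the total bending energy — the sliding step and the
recomputation of the mean as the plain average — so the energy trace is
non-increasing by construction; a final GPA re-superimposes the slid
configurations.  The classical variant that refreshes the GPA and the
bending-energy matrix every outer iteration is available
(`regpa_each_iter=True`); it converges to the same configurations on all
cohorts we generate but is monotone only to numerical tolerance.  Default: 3
outer iterations, relative energy tolerance 1e-8.  Sliding runs on the full
warp set (119 points); the shape analysis then re-superimposes the 69-point
subset, since a subset has its own similarity frame.

**Thin-plate splines.** Kernel U(r) = r² log r² with U(0) = 0; the bordered
system solves exactly (regularization defaults to 0, i.e. interpolation).
The bending-energy matrix used for sliding is the upper-left k × k block of
the inverse bordered kernel matrix; by construction it annihilates affine
displacement fields, and its quadratic form equals the wᵀKw energy of the
explicitly fitted spline (tested to 1e-8).

**Image registration.** Backward mapping: a TPS is fitted from the
mean-shape frame to the specimen's (slid) image landmarks, evaluated at every
frame pixel center, and the photograph is sampled bilinearly.  Slid landmark
positions are mapped back into each image by the least-squares similarity
between the aligned and digitized configurations.  The frame places the mean
shape into an H × W raster with a 10% margin (default 64 × 64 here; the
frame size is configurable and memory/time scale linearly in pixel count).
Eight border pseudo-landmarks (frame corners and edge midpoints, mapped
through the fitted similarity) stabilize the spline outside the landmark
hull.  Out-of-source-bounds samples take the boundary-clamped value and are
flagged in a mask; masked pixels are *not* excluded from statistics by
default.  Landmark files store y increasing upward while rasters index rows
downward; the single flip (row = H − 1 − y) lives in the sampling routines
and nowhere else.

**Statistics.** PCA is computed from the SVD of the centered data (Gram form
when p > n); all min(n−1, p) components are kept, the loading sign is fixed
by making each column's largest-absolute entry positive.  The covariate
effect on a block is the column-wise simple regression b = cov(X, x)/var(x);
effect scores project centered rows on b/‖b‖ and are, for a single covariate,
exactly proportional to first-dimension PLS scores (tested |r| = 1).
Reconstructions are data_mean + (x − x̄)·b, affine in x; texture
reconstructions are clipped to [0, 1] only at render time.  Prediction of the
covariate uses (a) the effect scores with a simple regression, (b) principal
component regression, and (c) ridge regression computed in the dual (kernel)
form when p > n, with the intercept unpenalized; the ridge penalty α is on
the raw scale of the centered Gram matrix.  As α → ∞ the ridge direction
converges to the cross-covariance Xcᵀxc, i.e. the multivariate-regression
axis.  All prediction accuracies are corrected by leave-one-out
cross-validation.  Significance of a multivariate regression is assessed by
permutation of the covariate (999 permutations by default, statistic =
within-sample score correlation, add-one p-value) — an assumption-light
choice for p ≫ n.

**Cross-validation scope.** The geometric stages (GPA, sliding, registration)
are computed once on the full sample and are blind to the covariates; only
statistical fits are refitted per fold.  PCR refits the PCA itself inside
every fold by default (`strict_cv`), since component selection is
covariate-adjacent; the score-based and ridge predictions refit their
regressions per fold.  The combined prediction recomputes each block's score
axis inside every fold before the multiple regression on the score columns.

## Synthetic cohorts and ground truth

The generator emulates the statistical structure of a standardized
photograph study: n = 49 specimens by default; BMI and WHR drawn from a
bivariate normal truncated by rejection to the observed ranges
(BMI mean 23.0, SD 4.0, range 17.0–35.4; WHR mean 0.72, SD 0.04, range
0.66–0.82; correlation 0.47).  Box truncation shifts means, shrinks SDs and
attenuates correlation, so the latent normal parameters are calibrated by
solving the five truncated-moment equations (Gauss–Legendre quadrature plus
root finding); the *truncated* population then has exactly the target
moments.

The face template is a deterministic schematic frontal face: 119 landmarks
(face outline, brows, eye contours, nose, lips, chin; plus vertex/head
outline, ears, hairline and neck points used only for warping), bilaterally
symmetric, with semilandmarks at near-equal arclength along nine curves.  Per
specimen the landmarks are template + BMI shape effect + three nuisance
factors + isotropic digitizing noise (SD 0.005 template units, where the face
half-width is 1), followed by a random similarity pose (±3° rotation, ±5%
scale, ±2% translation — small, as photographs are standardized to the
Frankfurt horizontal).  The BMI shape effect (0.006 units per kg/m²) widens
the outline and nose, lowers the brows, shrinks the eyes and thins the lips;
it is constructed normal to the curves at sliding semilandmarks and
orthogonal to the similarity directions.  Textures are painted procedurally
in the template frame (skin, hair, sclera/iris, lips, nostrils), with skin
brightness and redness increasing with BMI, per-specimen skin-tone jitter,
and pixel sensor noise, then TPS-warped onto the specimen's landmarks.

**What the ground truth means.** Sliding acts on small displacement fields as
the oblique projection S = I − T(TᵀMT)⁻¹TᵀM (T embeds the unit tangents, M is
the bending-energy form).  S converts part of *any* effect — even one normal
to the curves — into tangential repositioning, so the direction the full
protocol can recover is not the applied direction v but
w = unit(P_sub · restrict(S v)), where restrict takes the shape subset and
P_sub removes the subset's similarity components.  The exported ground truth
contains both v (as applied) and w (as recoverable); parameter-recovery
checks compare the estimated regression direction with w.  The oracle
correlation between BMI and the noise-free effect score follows in closed
form from the template geometry:
r = βg·σ_BMI / sqrt((βg·σ_BMI)² + (σ_d·h)²) with signal gain g = ‖P_sub R S v‖
and noise gain h = ‖Sᵀw‖.  The nuisance factors (face width, jaw size, brow
height) are Gram–Schmidt-orthogonalized against the similarity directions, v,
w, and Sᵀw, so they carry no variance along the scored direction and the
oracle stays exact; they still dominate the leading shape PCs.

**Signal-to-noise choice.** The defaults are set so that the effect direction
is identifiable from a single cohort: direction recovery to cosine ≥ 0.9 at
n = 200 with 138 coordinate dimensions mathematically requires the
coefficient-estimation noise (∝ sqrt(p/n)/σ_BMI per coordinate) to stay well
below the effect magnitude, which places the implied score correlation near
0.95.  Real face studies live at much lower correlations; the generator is a
validation instrument for the machinery, not a calibrated simulation of human
facial variation.  Consequences: passing recovery tests show the pipeline
estimates what the generator encodes, not that real-data effect sizes would
be recovered at these n.

**What the generator does not emulate:** photographic lighting and color-
calibration error, hair/background clutter, asymmetry, nonlinear covariate
effects, age/ethnicity structure, and correlated digitizing error along
curves.

## Numerical choices and degenerate inputs

- GPA: tol 1e-10 on RMS mean displacement, max 100 iterations; degenerate
  (all-coincident) configurations and collinear rank-deficient alignments
  raise.
- TPS: coincident source landmarks or collinear sources raise (singular
  bordered system); the sliding step falls back to least squares if the
  tangent normal-equation matrix is singular.
- Sliding tangents come from each specimen's own current point positions;
  coincident curve neighbors (zero tangent) raise, naming specimen and index.
- PCA drops numerically zero Gram eigenvalues (relative 1e-12); constant data
  raise.
- Ridge with α = 0 and p ≥ n raises (underdetermined) rather than returning a
  pseudo-inverse fit.
- Collinear score columns in the combined prediction are dropped with a
  warning (singular-value threshold 1e-10).
- Permutation p-values use the add-one estimator, so p ≥ 1/(n_perm + 1) > 0.

## Problem sizes used in the tests

Unit tests run on small synthetic matrices and cohorts (n ≤ 12, frames
32–48 px).  The end-to-end checks use n = 49–50 cohorts at 64 × 64 texture
frames, a n = 200 cohort for parameter recovery, a n = 400 landmark-only
cohort for the oracle comparison, 200 null cohorts for permutation
calibration, and 100 informative cohorts for the cross-validation optimism
check — sizes chosen so the full suite completes in about a minute on one
CPU while keeping Monte-Carlo error far below the tested tolerances.

## Known limitations

- Sliding is along straight tangent lines without re-projection onto the
  digitized curve; for large sliding displacements the points can leave the
  curve (the generator's cohorts slide by small amounts).
- The energy-descent guarantee holds for the default scheme (fixed alignment
  during relaxation); the classical re-GPA alternation is provided but not
  guaranteed monotone.
- The texture block is analyzed in raw RGB in [0, 1]; no color-space
  conversion is applied or planned, and no mask excludes hair/background
  pixels by default.
- LOOCV leaves the geometric stages fixed; a fully nested protocol would
  recompute GPA/sliding/registration per fold at substantial cost, and with
  covariate-blind geometry the leakage is negligible.
- 2D landmarks only; no missing-landmark estimation.
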
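# Methods

## Data model

A subject's observed sleeping energy expenditure (SEE) is modelled as

    y_it = f_i(x_it) + ε_it,   ε_it ~ N(0, σ²) i.i.d.,   t = 1..T minutes,

with f_i a smooth function of time since sleep onset.  Minutes are 1-based;
after windowing all subjects share the contiguous grid 1..405 (subjects with
fewer than 405 usable minutes are dropped, the rest truncated to their first
405 observed minutes).  SEE must be finite and strictly positive; minutes
with missing or non-numeric SEE are dropped from a subject's series but
counted, never silently discarded.

## Allometric normalisation

Energy expenditure scales multiplicatively with body size, so per-subject
mean SEE is fitted as SEE = exp(α + β·sex) · weight^β1 · height^β2 · age^β3 · ε,
linearised by natural log and estimated by OLS (statsmodels).  The pipeline
divides each series by weight^β1, with β1 snapped to the canonical 0.5 when
|β1 − 0.5| < 0.05 (reproduces the published convention on study-like data
while behaving sensibly elsewhere).  The regression is run on the windowed
cohort.  Because the adjustment is a per-subject scalar and the smoother is
linear, adjust-then-smooth equals smooth-then-adjust exactly; the test suite
asserts this to machine precision.

Sex is coded 0 = female / 1 = male (configurable in the ingest schema);
results are invariant to swapping the coding up to the sign of β.

## Smoothing

Curves are represented in a cubic B-spline basis (order 4) with equally
spaced interior knots and boundary knots at full multiplicity; coefficients
minimize (1/T) Σ_t (y_t − f(t))² + λ ∫ (f^(m))², default λ = 0 and m = 2.
Smoothness is controlled through the basis size K rather than λ, matching
the usual basis-expansion workflow: K = 40 by default.  K can be selected by
the greedy "myopic" ladder walk (default candidates 10, 20, 40, 80, 120):
compute mean GCV = (RSS/T)/(1 − K/T)² across subjects at each rung and stop
the first time the relative improvement drops below 0.05, returning the
previous rung.  The exact published stopping rule lives in an unavailable
supplement, so the criterion (GCV) and tolerance are configurable and
logged; a numerically zero criterion short-circuits the walk (exact fits).

All basis inner products (Gram and penalty matrices) use Gauss–Legendre
quadrature with order+1 nodes per knot span, exact for the piecewise
polynomials involved.  Degenerate inputs: λ = 0 requires T ≥ K observed
minutes; a singular penalized system raises with advice to raise λ or lower
K.

## Functional PCA

With curves f_i = c_i'φ and Gram matrix W = ∫ φφ', the covariance-operator
eigenproblem becomes the symmetric K×K problem
W^{1/2} [C_c'C_c/(n−1)] W^{1/2} u = μ u with eigenfunction coordinates
b = W^{−1/2} u.  Eigenfunctions are L²-orthonormal; scores
z_hi = b_h' W c_i^c are exact integrals, with sample mean 0 and diagonal
covariance diag(μ_h).  Variance proportions are taken over all min(n−1, K)
eigenvalues, not just the retained H (default H = 8).  Sign convention:
each eigenfunction is flipped so its integral over the domain is ≥ 0, ties
broken by the sign at the domain midpoint — eigenvectors are sign-ambiguous
and a fixed rule keeps results deterministic.

VARIMAX rotation maximizes the raw varimax criterion of the component values
on a 101-point equally spaced grid (Kaiser normalization off), via the
standard SVD iteration.  Rotated components remain orthonormal, rotated
score variances sum to the retained eigenvalue mass (asserted to 1e-8), and
components are re-ordered by decreasing rotated variance.

## Two-group tests

All functional tests evaluate the fitted curves on the integer-minute grid
and are calibrated by label permutation — B seeded permutations with
p = (1 + #{perm ≥ obs})/(B + 1); default B = 10,000.

* **Pointwise max-|t|**: Welch t at every minute; the adjusted p at minute t
  is the permutation proportion of max-over-grid |t| exceeding the observed
  |t(t)| (single-step Westfall–Young; controls FWER; adjusted ≥ raw by
  construction).
* **Functional F**: ∫ between-group SS dt / (G−1) over
  ∫ within-group SS dt / (n−G), trapezoid quadrature.  The within-group sum
  is accumulated from the per-group variances directly — subtracting the
  between-group term from the total cancels catastrophically for
  near-separated groups.
* **Adaptive Neyman**: the standardized difference curve (pooled-variance
  two-sample SE per minute; the published standardization is unspecified)
  is rotated by an orthonormal DCT and the statistic is
  max_m (1/√(2m)) Σ_{j≤m}(X_j² − 1), pooling an adaptive number of
  low-frequency coefficients.  Permutation calibration avoids the slow
  extreme-value asymptotics.
* **Hotelling T²** on the first H FPC scores uses its exact F reference
  (the one classical test here, per the MANOVA equivalence); it is invariant
  to any invertible linear map of the scores, hence identical for VARIMAX-
  rotated scores.

## Classification

Features: smoothed curves on the 405-minute grid (p = 405) or the first H
unrotated FPC scores; age/sex/height can be appended.  Classifiers (the
published analysis names the methods but no hyperparameters; these defaults
are documented assumptions): unpenalized logistic regression, RBF-SVM with
C = 1 and gamma = 'scale', random forest with 500 trees and √p features per
split.  Full-grid features are standardized within training folds for
logistic/SVM; forests see raw features.  Performance is the Monte-Carlo mean
over M = 1,000 runs (reducible; MC standard error ≪ 1 percentage point at
M = 200) of unstratified 10-fold CV mean fold accuracy, reproducible from a
single seed.  Logistic on full-grid data is refused as unidentifiable when
p ≥ the smallest training-fold size — the "NA" cell of the published
comparison table.

## Synthetic cohorts

Subjects in group g are drawn from a Karhunen–Loève model on the
weight-adjusted scale, X_i(t) = μ_g(t) + Σ_h √μ_h ζ_ih ξ_h(t) with
ζ ~ N(0,1), then observed as y_it = w_i^0.5 · X_i(t) + ε_it.  Defaults are
the stated study world:

* group sizes 44 obese / 62 non-obese, T = 405 minutes;
* μ_g(t) = baseline + 0.02·exp(−(t−1)/20) − 1.5e−5·(t−1)
  + 0.002·sin(2π(t−1)/180): a sharp post-onset drop, slow drift, and one
  subtle undulation, mimicking the observed nighttime shape.  Baselines
  0.127 / 0.132 kcal·min⁻¹·kg⁻⁰·⁵ make the time-averaged adjusted levels
  0.125 (obese) and 0.130 (non-obese), and with the lognormal weights below
  reproduce raw group means ≈ 1.05 / 0.86 kcal/min;
* two orthonormal modes (overall level; early-vs-late cosine contrast) with
  eigenvalues 0.04 and 0.017, so mode 1 carries ≈ 70% of the curve
  variance.  Modes are Gram–Schmidt-orthonormalized under the trapezoid
  inner product on the minute grid;
* weights lognormal matching 73.1 ± 27.0 kg (obese) and 45.0 ± 16.0 kg
  (non-obese); σ = 0.05 kcal/min white instrument noise (calorimeter-like);
* negative draws are clipped at a positive floor, with a warning when more
  than 1% of values clip.

A blank-room generator produces constant-signal noise-only traces (five
9-hour runs by default), emulating the gas-infusion validation experiment,
for testing that smoothing suppresses noise without introducing artifacts.

What the generator does **not** emulate: REM/NREM cycling or circadian
structure within the night, heteroscedastic or autocorrelated instrument
noise, awakenings/missing-minute patterns, or covariate-SEE relationships
beyond weight (age/height/sex are drawn independently).  A green test
therefore establishes correctness of the statistical machinery under the
stated model, not physiological fidelity; with only two true modes the first
two components explain ~97% of variance in synthetic runs, unlike real
cohorts where the tail is heavier.

## Numerical choices

* Permutation p-values include the +1 correction and use ≥ comparisons;
  the minimum attainable p is 1/(B+1) (only approached when group sizes make
  re-drawing the observed labeling negligible).
* FPCA eigenvalues are clipped at 0; the Gram matrix must be positive
  definite (it is, for any valid B-spline basis).
* The score/eigenfunction oracle tests use independent dense-grid
  quadrature (trapezoid for the PCA oracle, Simpson for score integrals).
* All randomness flows through `numpy.random.default_rng` seeds; same seed,
  same bytes.

## Known limitations

* Subjects with interior gaps are re-indexed onto the common grid by taking
  their first 405 observed minutes, rather than re-gridding through the
  smooth; for gap-free data the two conventions coincide.
* The myopic K selector's published details are unavailable; on data unlike
  the study's the selected K should be inspected via the returned trace.
* The adaptive Neyman standardization choice shifts its p-values somewhat;
  conclusions should rest on the permutation calibration, not asymptotics.
* Full-budget runs (B = 10,000, M = 1,000, 500-tree forests on full grids)
  take tens of minutes on one CPU; the acceptance script scales these down.
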
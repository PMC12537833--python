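# Methods

## The decoding model

Each sample is one cue block's beta map **x** ∈ ℝᵖ (p voxels, Fortran flat
order, zero off-mask) with metadata (subject, block index, cue type
drug/neutral, craving rating y ∈ {1,2,3,4}). The fitted pipeline is

1. **Variance filter.** Keep column j iff its unbiased sample variance
   (ddof = 1) is ≥ 0.001. This removes off-mask and dead voxels before any
   scaling; the threshold being positive guarantees every surviving column
   has a nonzero scale.
2. **Standardization.** z = (x − μ)/σ per kept column, with μ, σ estimated
   on the training rows only (population σ, as a standard scaler computes).
3. **Projection.** PCA: S = Z Vᵀ with V the top-k eigenvector matrix of
   the scaled training data (k = 100 for the regression and cue tasks, 50
   for high/low). ANOVA alternative: keep the k columns with the largest
   one-way F statistic of z grouped by rating level.
4. **Regression.** ŷ = S·B + b₀, ordinary least squares by default. Ridge,
   lasso, elastic net, random forest and gradient-boosted trees fill out
   the model-selection menu; the grid search scores every (reducer,
   regressor) candidate by subject-level 5-fold CV stratified RMSE and ties
   break toward fewer components, then the simpler family.

The raw regression output is never clipped to [1, 4]: the two binary
readouts threshold it downstream.

**Back-projection.** For a PCA + linear fit, vb = Vᵀ B is the signature in
standardized voxel space; vb_raw = vb/σ scattered to the full grid, with
the adjusted intercept b₀′ = b₀ − Σ μ vb/σ, satisfies
ŷ = ⟨x_raw, vb_raw⟩ + b₀′ exactly (asserted to 1e-8 in tests across
families and seeds). The `vb` variant (no 1/σ) is what figures and the
regional summary use; `vb_raw` is the prediction-equivalent form. Display
normalization rescales the map so ‖vb_raw‖₂ matches the cohort's mean beta
map norm; only the scale changes. Regional summaries average `vb` over each
parcellation region's in-mask voxels; regions without in-mask voxels are
omitted rather than reported as zero.

## Validation scheme

Splitting is always by subject: the hold-out set is ⌈0.2·n⌉ subjects
(ceiling, so 51 → 11 held-out + 40 fitting), and the remaining subjects
are dealt into 5 folds whose sizes differ by at most one. A leakage
assertion re-checks every fold at the sample level and trips on planted
duplicate subjects.

RMSE and MAE are stratified — computed within each observed rating level,
then averaged without weights. Pearson r is pooled over all pairs because a
within-level correlation is undefined whenever the level's true ratings
are constant; a blanket "stratified correlation" cannot be computed. The
"mean ± SD" metric distributions are built by repeating the 5-fold CV with
fresh fold assignments (default 100 repetitions; the repetition count is a
package choice — each repetition contributes its pooled out-of-fold
metric). The hold-out is scored once, by a final pipeline fit on all
fitting subjects.

## Inference

The null distribution shuffles the prediction targets across all fitting
samples (features untouched) and re-runs the full CV per permutation
(default 1000; a within-subject shuffle is available as a config flag).
Because the PCA reducer never sees the targets, per-fold transforms are
cached across permutations, and for the OLS family all permuted targets
are solved in one multi-RHS least-squares call per fold — a test verifies
this equals the naive per-permutation refit to 1e-10.

* **p-value:** add-one rule, p = (1 + #{null at least as good as the
  observed mean})/(1 + n_perm), so p is never 0 and is uniform under the
  null (verified empirically: rejection rate at α = 0.05 stays within
  5 % ± 4 points over 200 label-shuffled cohorts).
* **Power:** fraction of the observed distribution beyond the null's 5 %
  critical value (counting definition; power ≈ α when observed ≡ null).
* **Effect size:** Shapiro–Wilk (α = 0.05) on the observed distribution
  gates Cohen's d + Student-t CI (normal) vs. Cliff's δ +
  percentile-bootstrap CI (otherwise). The effect compares the observed
  to the null distribution and is sign-oriented so that "better than
  null" is positive for both lower-better and higher-better metrics.

## Binary readouts

**High/low craving.** Per subject, only the first occurrence (in block
order) of the minimum and of the maximum rating are kept; subjects with
constant ratings are dropped (no contrast), so classes are exactly
balanced. The regressor is still trained on the raw 1–4 ratings of those
extreme blocks with 50 PCA components (the extreme subset halves the
sample count); the continuous output is binarized with the F1-optimal
threshold, searched over midpoints of consecutive sorted unique training
predictions plus one flanking candidate on each side, re-fit on each CV
iteration's *training* predictions (optimizing on test would leak), ties
resolving to the lowest threshold. RMSE for this task scores the raw
predictions against the raw extreme ratings — consistent with that task's
error magnitudes being on the 1–4 scale rather than 0/1.

**Cue type.** The regression target is the 0/1 cue code; outputs are
binarized at a fixed 0.5, boundary to the drug class, 100 components.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes, not
real physiology. Per subject s and block b with cue c:

    betas_b  = mask ∘ [ε_b + a_c·w_true + o_s·1]
    latent_b = ⟨betas_b, w_true⟩ + o_s + η_b
    rating_b = 1 + #{thresholds ≤ latent_b}

with ε per-voxel N(0, noise_sd), η N(0, noise_sd), o_s N(0, subject_sd),
and w_true a unit-norm vector on a random sparse support inside a central
spherical mask. Defaults: 69 subjects, 18 excluded (the emulated cohort
arithmetic), 8 alternating blocks starting neutral (6 images × 5 s +
5 × 0.2 s gaps = 31 s each, TR 2 s, 196 volumes), 4096 voxels on a 16³
grid with 60 % in-mask — a desk-scale stand-in for the >10⁶-voxel brain
grid, configurable upward — support 128, amplitudes a_drug = 2.5 >
a_neutral = 1.0 (so drug blocks rate higher on average), subject_sd 0.4,
noise_sd 0.5, rating thresholds (1.0, 1.75, 2.5), chosen so the rating
marginal covers all four levels at the default noise. Randomness flows
from one seed through a spawned child-seed tree (global stream, then one
per subject, then one per block), so identical seeds give bit-identical
cohorts. Exclusion is an ID filter applied before any split. Thresholds
that collapse all ratings to one level raise a warning rather than fail
silently.

What the generator does **not** emulate: spatial autocorrelation and
smoothness, hemodynamics, scanner drift, motion artifacts, anatomically
structured signatures, or realistic rating marginals (empirical marginals
vary across studies; the default thresholds are calibrated only to cover
all four levels). Passing tests therefore demonstrate the
correctness of the pipeline's algebra, splitting, calibration and
recovery behaviour — not expected performance on real data.

## Numerical choices

* Fortran (x-fastest) flat voxel order everywhere; volumes stored float32,
  computation float64; affines preserved bit-exactly through round trips.
* PCA via scikit-learn's SVD with `random_state=0`; component signs are
  re-fixed by forcing each component's largest-magnitude loading positive,
  making signature maps identical across repeated fits.
* The ANOVA branch is standardized with the same scaler as PCA (uniform
  treatment) and groups by rating level; top-k ties break on column index.
* Grid-search tie-break: fewer components, then family order
  (ols, ridge, lasso, elastic net, random forest, gradient boosting).
* Degenerate inputs: constant prediction/target vectors make Pearson r
  undefined — reported as NaN, not an exception; single-class folds make
  AUCs NaN; constant observed distributions collapse the CI to a point.
* Extreme-block threshold candidates include one value below the minimum
  and above the maximum prediction so "always negative"/"always positive"
  are reachable decisions.
* "Gradient boosting" is scikit-learn's implementation; the menu
  reproduces the model-selection experiment, whose winner is PCA + OLS,
  rather than any specific boosting library.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale: 512-voxel
(8³) grids for unit tests; 4096 voxels with 40–69 subjects for
calibration, recovery and the end-to-end quantities; 50–100 CV
repetitions; 200 permutations; 100–200 calibration repetitions. All sizes
scale up through `SyntheticConfig` and `RunConfig` without code changes.

## Known limitations

* The permutation fast path requires the PCA + OLS configuration; other
  families fall back to a per-permutation loop, and the high/low null is
  defined for PCA + OLS only.
* No voxelwise multiple-comparison correction is applied to signature
  maps (none is part of the procedure); regional rankings are descriptive.
* No spatial resampling or registration: inputs are assumed co-registered
  on a shared grid.
* The bootstrap CI is a simple percentile interval of the resampled mean;
  no BCa correction.
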
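# cravemap

Voxel-based decoding of subjective drug craving from fMRI cue-reactivity
beta maps.

In a cue-reactivity experiment, a participant with a substance use disorder
views alternating blocks of drug-related and neutral images while being
scanned, and after every block reports their momentary craving on a 1–4
scale. A general linear model turns each block into a **beta map** — one
coefficient per voxel estimating that block's BOLD response. `cravemap`
implements the full multivariate analysis that links those maps to the
ratings:

* **Feature reduction** — drop voxels with sample variance < 0.001,
  standardize, then project onto PCA components (or select top-k voxels by
  one-way ANOVA F across rating levels).
* **Regression** — predict the rating from the reduced scores with
  y&#770; = S·B + b₀ (ordinary least squares by default; ridge, lasso, elastic
  net, random forest and gradient boosting are available through a
  grid search that minimizes cross-validated RMSE).
* **Subject-level validation** — a 20 % subject hold-out plus 5-fold CV in
  which all blocks of a subject stay on one side of every split; error
  metrics are *stratified* (computed per rating level, then averaged) to
  neutralize label imbalance.
* **Permutation inference** — shuffling the targets across samples and
  re-running the CV builds each metric's null distribution; the add-one
  permutation p-value, counting statistical power at the 5 % critical
  value, and a Shapiro–Wilk-gated effect size (Cohen's *d* / Cliff's δ
  with Student-t / bootstrap CI) summarize each metric.
* **Signature back-projection** — for a PCA + linear model, the product
  **VB** of the eigenvector matrix V and coefficient vector B is a voxel
  map of each voxel's contribution to predicted craving; it is normalized
  to the norm of the mean beta map for display and averaged within the
  regions of an integer-labeled parcellation (e.g. a 246-region atlas).
* **Binary readouts** — the same pipeline classifies **high vs. low
  craving** (per subject, only the first-occurrence minimum- and
  maximum-rating blocks; F1-optimal threshold re-fit on each iteration's
  training predictions; 50 PCA components) and **drug vs. neutral cues**
  (0/1 target, fixed 0.5 threshold, 100 components).

Real cue-reactivity datasets are rarely public, so the package ships a
first-class synthetic generator: cohorts of block-level beta maps with a
planted sparse voxel signature, subject offsets, and ratings derived from
the same latent signal, reproducing a typical study's shape (69 recruited
subjects, 18 excluded, 8 alternating 31-s blocks starting with a neutral
one). Every stage is tested against it, including recovery of the
planted signature.

## Worked example

```python
from cravemap import (SyntheticConfig, generate_cohort, apply_exclusions,
                      make_split, run_cv, fit_pipeline, back_project,
                      normalize_for_display, summarize_by_atlas,
                      synthetic_parcellation)

cfg = SyntheticConfig(seed=1)                      # 69 subjects, 16^3 grid
cohort, truth = generate_cohort(cfg)
analyzed = apply_exclusions(cohort, truth)
print("analyzed subjects:", len(analyzed.subjects))

plan = make_split(analyzed.subjects, holdout_fraction=0.2, k=5, seed=1)
print("hold-out / fitting:", len(plan.holdout_subjects), "/", len(plan.fitting_subjects))

fitting = analyzed.select_subjects(plan.fitting_subjects)
res = run_cv(fitting, {"method": "pca", "n_components": 100}, seed=1)
print("stratified RMSE: %.3f   pooled r: %.3f"
      % (res.pooled["rmse_stratified"].value, res.pooled["pearson_r"].value))

pipe = fit_pipeline(fitting.X, fitting.ratings, {"method": "pca", "n_components": 100})
sig = normalize_for_display(back_project(pipe), fitting.mean_beta_map())
atlas = synthetic_parcellation(fitting.stack, n_regions=246, seed=0)
print(summarize_by_atlas(sig, atlas, fitting.stack).head(3).to_string(index=False))
```

prints

```
analyzed subjects: 51
hold-out / fitting: 11 / 40
stratified RMSE: 0.880   pooled r: 0.570
 region_id region_name  mean_vb  n_voxels  rank
        19  region-019 0.055104         6     1
       232  region-232 0.040383         5     2
       130  region-130 0.031999         4     3
```

51 analyzed subjects split 11/40; the out-of-fold stratified RMSE of 0.88
rating points and pooled Pearson r of 0.57 show the decoder recovering the
planted rating signal at the generator's default signal-to-noise level,
and the regional table ranks the parcels that carry the strongest positive
signature weight.

The same analysis runs from a shell:

```bash
cravemap report --seed 1 --out out/            # full pipeline + stat table
cravemap simulate --seed 1 --out data/         # write the cohort as NIfTI + TSV
cravemap classify-cue --seed 1 --out out-cue/  # drug/neutral readout
```

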
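# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limits of what the test suite demonstrates.

## Normative model and deviation index

Per diffusion metric (FA, MD, RD, AD), a regressor trained on typically
developing (TD) children maps per-bundle mean features to chronological
age. The default is support-vector regression with an RBF kernel
(C = 1.0, ε = 0.1), features standardized with training-set statistics
only; a random-forest variant (500 trees, seed-controlled) is provided to
show results are not model-specific. The feature granularity fed to the
model is configurable (`global_mean`, `bundle_means`, `voxel_vector`);
`bundle_means` is the default since per-bundle means are the natural
TBSS-derived summary and keep the model well-posed at n ≈ 27 training
subjects.

Raw brain-age gaps regress to the mean: the youngest subjects are
overestimated and the oldest underestimated. We therefore fit, on a
held-out TD test set (default split fraction 0.5, rank-sum age-matched
with a sorted-alternation fallback), the linear trend of the raw gap on
true age Ω and subtract it:

    bias_free(Ω) = (predicted − Ω) − (α·Ω + β)

By construction the corrected gap has exactly zero least-squares slope on
the estimation set (verified to < 1e-10). The sign convention is
positive = accelerated maturation. The same α, β are then applied to the
autistic (ASD) subjects, whose corrected gaps form the subjects × 4
"WM atypical development index" matrix.

Two algebraic forms of this correction circulate, differing in sign; we
implement the Beheshti-style scheme (fit the raw gap on age in
held-out controls, subtract the fitted value), which is the only
self-consistent reading and is what the identity test pins down.

## Subtyping

k-means (k-means++ seeding, 50 restarts, best inertia) on the
*unstandardized* 4-column index matrix — all columns share year units, so
rescaling is not required; a z-scoring toggle exists. The cluster count is
selected by the mean silhouette coefficient over k = 2…10 (singletons
score 0; ties break toward smaller k for parsimony). For reporting,
clusters are relabeled so subgroup 1 is the younger one. Downstream
comparisons: pooled-variance t-tests (age, head motion, each metric's
index with BH-FDR over 4 tests, ADOS total/social excluding subjects with
missing ADOS), chi-square for sex/handedness, and partial correlation of
index with age controlling sex, handedness and head motion (the nuisance
set used elsewhere in the pipeline, minus age itself; the covariate list is
configurable).

## Voxelwise statistics

Per voxel, ordinary least squares on a design [intercept | group |
nuisance] with t = cᵀβ̂ / √(σ̂² cᵀ(XᵀX)⁻¹c). Constant nuisance columns are
dropped (e.g. single-handedness subsamples). TFCE integrates
extent^E · height^H · dh over a threshold ladder; defaults E = 0.5, H = 2,
26-connectivity, dh = max|stat|/100, with a skeleton-optimized preset
(E = 1, H = 2). Both signs are enhanced (the negated map is processed and
returned with negative sign), since the subgroup contrasts are genuinely
bidirectional. Family-wise error control uses the permutation distribution
of the maximum |enhanced| statistic with Freedman–Lane permutation of
reduced-model residuals, so nuisance effects are respected; the observed
(identity) relabeling is always counted alongside the n_perm random draws,
giving p(v) = (1 + #{null_max ≥ |tfce(v)|}) / (1 + n_perm) ∈
[1/(n_perm+1), 1]. For each subgroup the TD pool is re-age-matched with
the greedy matcher before the contrast.

Greedy matching itself deletes, at every step, the single participant
(from either group; ties prefer the larger group, then the lowest id)
whose removal maximizes the rank-sum p of the age difference, stopping at
p > 0.1 or at a configurable minimum group size (3).

## Synthetic cohort

The generator emulates the statistical structure the pipeline assumes, on
a 16×16×8 grid (2 mm isotropic, RAS+) carrying a one-voxel-thick skeleton
sheet split into 8 contiguous bundles — real TBSS skeletons are sparse
sheets, and a sheet keeps permutation testing desk-scale.

Defaults (all configurable through `CohortSpec`):

- 54 TD / 68 ASD subjects, ages uniform on 4–7 y (no empirical age
  distribution is prescribed, so the simplest one is used).
- TD voxel means: baseline + slope·age with FA +0.012/y and MD/RD/AD
  −0.020/−0.022/−0.018 µm²/ms per year; baselines put MD near 0.9 µm²/ms.
  Diffusivities are expressed in µm²/ms to keep arithmetic O(1).
- ASD trajectories use the attenuated slope (fraction 0.5) *pivoting at
  the age-range center*, so the groups coincide in overall mean and the
  case–control comparison of global means is null by construction — the
  masking phenomenon the deviation approach exists to overcome.
- Two latent ASD subgroups assigned by a logistic function of age centered
  at 5.5 y (scale 0.20 y): subgroup 1 dominates below, subgroup 2 above.
  Subgroup 1 receives +0.015 FA / −0.022 MD,RD,AD offsets on 6 of the 8
  bundles (regional effects in this population typically span a handful of tracts);
  subgroup 2 the mirror image.
- Noise: per-voxel Gaussian (FA 0.040, diffusivities 0.050) plus a
  per-subject, per-metric global offset (FA 0.003, diffusivities 0.004)
  that does not average out across bundles.
- ADOS per subgroup (total 17.5/19.5 ± 4; social 7.5/9.5 ± 1.8, subgroup 2
  higher), with a missing fraction of 8/68; head motion ASD 0.24 ± 0.05 mm
  vs TD 0.35 ± 0.12 mm; sex and handedness frequencies match the cohort profile the generator
  targets (47M/21F and 59R/3L/6M in the ASD group, 33M/21F and 48R/1L/5M
  in TD).
- A single global seed feeds per-subject child streams
  (`SeedSequence.spawn`), so enlarging a cohort never reshuffles existing
  subjects.

The offset and noise magnitudes were fixed by a one-time calibration so
that the default cohort actually contains the structure the downstream
stages are specified to recover (two silhouette-separable subgroups,
negative index–age correlations, mirror-image voxel effects). One finding
from that calibration is worth recording: very large regional offsets push
ASD feature vectors outside the TD training distribution, where the RBF
kernel saturates and predictions collapse toward the training mean —
spreading a smaller offset over more bundles is both more faithful to the
tract-level picture and numerically better behaved.

What the generator does **not** emulate: registration and projection
artifacts, spatially correlated noise, partial-volume effects, site/
scanner differences, non-uniform age sampling, or any nonlinearity in the
maturational trajectories. Consequently the synthetic cross-validation
errors (MAPE ≈ 4–7%) are better than one should expect on clinical data,
and passing tests demonstrate correctness of the *procedures* — not that
real cohorts will show effects of these magnitudes.

## Numerical choices and degenerate inputs

- Rank-sum test: exact enumeration when combined n ≤ 12 without ties;
  otherwise normal approximation with midranks and tie-corrected variance;
  an all-tied comparison returns p = 1.
- t-tests are pooled-variance (the equal-variance assumption is flagged in
  result metadata); zero pooled variance with equal means gives t = 0,
  p = 1, with unequal means it is an error.
- Partial correlation: residualize both variables on [intercept |
  covariates] (constant columns dropped), test with n − 2 − k df;
  collinearity with covariates raises rather than returning NaN.
- BH-FDR via the standard step-up; the deviation comparisons fix the
  family size at the 4 metrics.
- TFCE uses an integer-indexed threshold ladder (h = i·dh) with a 1e-12
  comparison tolerance so the top threshold is never lost to float drift.
- All stochastic stages take explicit seeds; the pipeline manifest records
  the configuration hash and seeds, and identical configurations reproduce
  identical outputs byte-for-byte.

## Problem sizes

Simulation-backed tests use reduced sizes chosen as a deliberate design
point: 8×8×4 grids and 16–24 subjects per group for permutation tests,
n_perm = 200 for null calibration (200 repetitions, empirical CDF of the
minimum corrected p at 0.05 required ≤ 0.08) and n_perm = 500 for the
planted-effect power check; the subtype-recovery and model-selection
checks run the full default cohort over 20 seeds. The acceptance script
repeats the default-cohort pipeline 20 times and reports the modal
silhouette-selected cluster count.

## Known limitations

- The pipeline is cross-sectional; no longitudinal or mixed-effects
  modeling.
- Matching is greedy, not optimal; it can remove more participants than an
  exhaustive search would.
- SVR hyperparameters are fixed defaults, not tuned per metric; with
  ~27 training subjects a search would overfit.
- TFCE connectivity and mode (volumetric vs skeleton-optimized) are
  presets; on a one-voxel sheet the 26-connectivity volumetric default
  behaves like a surface parameterization.
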
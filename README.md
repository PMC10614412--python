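# wmdev

Developmental deviation analysis of white-matter diffusion metrics in
pre-school children.

## The problem

Between ages 4 and 7 the white matter of typically developing children
matures rapidly and near-linearly: fractional anisotropy (FA) rises while
mean, radial and axial diffusivity (MD, RD, AD) fall. In autistic children
this trajectory is flattened, and — crucially — the *direction* of any
regional difference from controls flips with age: younger autistic
children tend toward an overgrowth pattern (FA up, diffusivities down),
older ones toward delayed maturation (the mirror image). A plain
case–control comparison averages these opposite effects away and finds
nothing. `wmdev` implements the deviation-based workflow that resolves
this heterogeneity, for researchers analyzing skeleton-space (TBSS-style)
scalar maps with a phenotype table.

## The method

1. **Greedy age matching.** Starting from both groups, delete one
   participant at a time — always the one whose removal leaves the highest
   two-sided Wilcoxon rank-sum p-value for the age difference — until
   p > 0.1.
2. **Normative age prediction.** Per metric, train a regressor (RBF
   support-vector regression by default; random-forest regression as a
   robustness variant) on control subjects' per-bundle mean features to
   predict chronological age. Performance is reported as fivefold
   cross-validated MSE (y²) and MAPE (%).
3. **Bias-free deviation.** Brain-age gaps are age-biased (overestimated in
   the youngest, underestimated in the oldest). On a held-out control test
   set, regress the raw gap on true age Ω:

       deviation      = predicted − Ω
       bias_free      = deviation − (α·Ω + β)

   The corrected value — one per metric per subject — is the **WM atypical
   development index**: positive = accelerated maturation, negative =
   delayed.
4. **Subtype discovery.** k-means on the autistic subjects' 4-column index
   matrix; the number of clusters is chosen by the mean silhouette
   coefficient over k = 2…10. Subgroups are compared on age, deviation
   (BH-FDR over the 4 metrics), ADOS scores, sex and handedness, and the
   index is related to age by partial correlation (controlling sex,
   handedness, head motion).
5. **Voxelwise stage-specific statistics.** Each subgroup is contrasted
   against a re-age-matched control subset with a voxelwise GLM
   (nuisance: age, sex, handedness, head motion), threshold-free cluster
   enhancement (TFCE, E=0.5, H=2, 26-connectivity; a skeleton preset with
   E=1 is provided), and family-wise error correction from the permutation
   distribution of the maximum enhanced statistic under Freedman–Lane
   residual permutation.

Because clinical diffusion cohorts of this age group are rarely shareable,
the package ships a first-class synthetic cohort generator
(`wmdev.synthetic_cohort`) that emulates the statistical structure above —
age trajectories, two latent subgroups with opposite regional offsets, an
age-linked subgroup boundary, ADOS and head-motion differences — so the
entire pipeline is testable end-to-end without any data download.

## Worked example

```python
from wmdev import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="out", seed=1, n_perm=100)
results = run_pipeline(cfg)
print(results["report"])
```

This simulates the default cohort (68 autistic / 54 control children,
ages 4–7 y), runs every stage, and prints, among other tables:

```
Age-model cross-validation (5-fold)
-----------------------------------
  FA: MSE = 0.20 y^2, MAPE = 6.98%
  MD: MSE = 0.07 y^2, MAPE = 4.16%
  RD: MSE = 0.08 y^2, MAPE = 3.92%
  AD: MSE = 0.12 y^2, MAPE = 5.11%

Silhouette selection: chosen k = 2 (mean silhouette 0.784)

Subgroup comparison (1 = younger)
---------------------------------
      variable test  statistic            p    mean_1    mean_2
     age_years    t -12.062488 2.389765e-18  4.739012  6.120898
  deviation_FA    t  24.970204 2.425419e-35  1.003574 -0.960502
   ados_social    t  -5.423186 1.238995e-06  6.990967  9.464434
```

Reading: the silhouette criterion selects two clusters; subgroup 1 is
younger with *positive* deviation indices (accelerated maturation) and
subgroup 2 older with negative ones (delayed), and subgroup 2 carries the
higher ADOS social scores. The per-bundle voxelwise table shows the mirror
pattern: subgroup 1 has FA significantly *above* matched controls and
diffusivities below, subgroup 2 the reverse.

The same stages are available from a shell via the `wmdev` CLI
(`wmdev run --out out --seed 1`, plus `simulate`, `match`, `brainage`,
`subtype`, `voxelstats`, `report` subcommands).

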
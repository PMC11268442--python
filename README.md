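# methylgrowth

Gene-level DNA-methylation analysis of infant growth: from array
intensities to methylation risk scores.

Small birth cohorts with paired methylation arrays (cord blood, placenta)
and longitudinal anthropometrics are used to ask whether methylation at
birth predicts weight outcomes at six months. The per-CpG dimensionality
(hundreds of thousands of probes) overwhelms a 48-child cohort, so the
analysis aggregates CpGs to gene-body means and selects predictive genes
with penalized regression. `methylgrowth` implements that pipeline
end-to-end, together with a synthetic cohort generator for validating every
stage against known truth.

**Pipeline stages**

1. **Preprocessing** — Beta values `β = M/(M+U+100)` from methylated /
   unmethylated intensities; background, SNP and sex-chromosome probe
   filters; low-quality sample screen; BMIQ normalization (three-state beta
   mixture fit per design type, quantile mapping of Infinium II onto
   Infinium I states, strictly rank-preserving).
2. **Outcomes** — conditional weight gain z-scores (standardized residuals
   of six-month weight-for-age z on birth weight-for-age z with length and
   exact age as covariates; mean 0, SD 1 by construction), six-month BMI
   (kg/m²) and weight-for-length (kg/m), the latter two standardized by sex.
3. **Gene aggregation** — probes mapped to BED intervals (0-based
   half-open; 1-based probe positions converted), gene value = mean Beta of
   member CpGs.
4. **Selection** — cross-validated LASSO (penalty at the CV-MSE minimum),
   repeated with fresh fold seeds until ten "check-mark" CV curves are
   collected; consensus = genes selected in ≥ 6/10 runs; post-selection OLS
   de-biases coefficients and supplies p-values; covariate screening and
   CpG-site-level re-analysis included.
5. **Methylation risk scores** — `MRS_j = Σ_i w_i c_ij` with post-OLS
   coefficients as weights; in-sample association, and frozen-weight
   transfer to an external cohort with per-gene marginal and joint
   regressions.

## Worked example

Select genes on a 200-child synthetic cohort with five planted effects
(|effect| = 0.5 on standardized gene methylation) and build the risk score
(`examples/04_select_genes.py`, `examples/05_mrs_transfer.py`):

```text
10 check-mark runs in 10 attempts; consensus = 21 genes (q=6/10)
causal genes recovered: 5/5  false positives: 16

post-selection OLS adjusted R^2 = 0.836
gene        planted   joint coef   p-value    marginal coef
G00043    -0.50      -10.600   5.69e-30     -10.482
G00448    -0.50      -10.697   1.13e-24     -11.230
G00031    +0.50      +10.676   2.33e-24     +11.351
G00341    +0.50       +9.657   1.50e-23     +10.632
G00044    +0.50       +9.081   1.37e-22      +8.484
G00322    +0.00       -3.573   1.19e-04      -5.092
...
```

All five planted genes are recovered; selection at the CV-MSE minimum is
deliberately liberal, and the post-OLS p-values separate planted genes
(p ≤ 1e-22) from the liberally admitted extras (p ~ 1e-2…1e-4) — the joint
coefficients are on the Beta scale, so ±10 per unit Beta ≈ ±0.1 per 0.01
methylation change. The corresponding risk score behaves as the theory
says it must:

```text
in-sample: 28 genes, MRS adjusted R^2 = 0.8526 (joint post-OLS: 0.8526)
transfer (shared causal structure): slope p = 1.22e-59, adj R^2 = 0.589
transfer (null cohort):              slope p = 0.64, adj R^2 = -0.003
```

In-sample the MRS association equals the joint post-OLS fit exactly (the
score is the fitted value minus the intercept); with frozen weights it
stays predictive on a cohort sharing the causal structure and collapses to
noise on a cohort whose outcome is independent of methylation.

The full two-tissue orchestration (2 tissues × 3 outcomes = 6 selection
regressions) runs via `examples/06_full_pipeline.py` or the CLI:

```bash
methylgrowth demo --seed 1 --out-dir demo_run
methylgrowth run-all --config my_run.yaml
```

Each stage is also a subcommand (`simulate`, `preprocess`, `outcomes`,
`aggregate`, `select`, `mrs score|transfer`) reading and writing plain-text
formats (TSV/BED/CSV/JSON), and every run writes a manifest with content
checksums for each artifact.

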
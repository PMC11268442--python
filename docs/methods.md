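# Methods

`methylgrowth` implements a gene-level analysis linking DNA methylation at
birth (cord blood, placenta) to infant weight outcomes at six months, plus a
synthetic cohort generator that emulates the statistical structure such a
study assumes. This note documents the models, the tunable parameters, the
numerical choices, and what the synthetic data does and does not show.

## Beta values and probe/sample QC

Array intensities are summarized per CpG as

    beta = M / (M + U + 100)

with M and U the methylated and unmethylated channel intensities; the +100
offset keeps low-intensity probes away from the boundaries, so beta is in
[0, 1). QC stages, each logged with in/out/removed counts:

- **Background filter** — a probe is dropped when both channels are strictly
  below a threshold (default 50, above the generator's noise floor of ~40)
  in a configurable fraction of samples (default: all). Equality with the
  threshold retains the probe. This is an inspectable stand-in for
  detection-p-value filtering, which needs control probes the pipeline does
  not model.
- **Annotation filters** — probes flagged as SNP-overlapping or on a sex
  chromosome are dropped (union of the flags).
- **Sample screen** — samples whose median log2 total intensity falls below
  a threshold (default 10.0 on the synthetic scale) are removed. The rule is
  a deliberate simplification: "low quality" has no canonical definition,
  and the threshold is exposed in the run config.

The background and annotation filters commute: the surviving probe set does
not depend on their order.

## Three-state beta mixture and BMIQ

Within a sample, Beta values are modeled as a 3-component beta mixture
(unmethylated / hemimethylated / methylated). The EM fit uses:

- values clamped to [1e-6, 1 − 1e-6] so the beta likelihood stays finite;
- initialization by moment-matching the data split at fixed cut points
  (0.25, 0.75);
- an exact M-step per component (L-BFGS on (log a, log b) with analytic
  gradients, from sufficient statistics, never accepting a step that lowers
  the component objective) so the log-likelihood is nondecreasing;
- relabeling by increasing component mean, and state thresholds located
  where the maximum-posterior state changes on a fine grid;
- convergence at a relative log-likelihood change below 1e-5 (default),
  max 200 iterations; non-convergence returns the best fit with a warning.

BMIQ normalizes the Infinium II design to the Infinium I design per sample:
mixtures are fitted to each design (on a seeded subsample of at most 8000
values when larger — the mapping itself is applied to all probes),
unmethylated-state and methylated-state type II values are quantile-mapped
through the fitted state beta distributions onto the type I states, and
hemimethylated values get an affine dilation pinned to the two mapped state
boundaries. Because each piece is strictly increasing and the pieces agree
at the thresholds, the transform is globally strictly monotone: ranks within
a sample's type II probes are exactly preserved. Type I probes pass through
bit-identical, and outputs are clipped to [0, 1].

## Weight outcomes

Three outcomes per child:

- **Conditional weight gain (CWG) z-score** — standardized residual of an
  OLS regression of the six-month weight-for-age z-score (WAZ) on birth WAZ,
  with length-for-age z-scores at both ages and exact age at the six-month
  visit (days) as covariates. Residuals are divided by their sample SD
  (ddof = 1), so the cohort mean is 0 and SD is 1 exactly. Adding a constant
  to the six-month WAZ leaves CWG unchanged (absorbed by the intercept).
- **BMI at six months** — weight / (length in m)²; **weight-for-length** —
  weight / length. Both standardized by sex (per-sex mean 0, sample SD 1)
  before gene selection, because sex is the one covariate robustly
  associated with them. CWG needs no sex standardization: sex-linked
  variation enters both WAZ terms and cancels in the residual.

Growth-reference z-scores (WAZ/LAZ) are accepted as input columns when
available; when absent the pipeline falls back to within-sample
z-standardization of the raw measures at each age, with a loud log message —
the fallback preserves the regression structure but is not a
reference-based z-score. Sample SDs (ddof = 1) are used everywhere. A
Shapiro–Wilk normality table is available as a report-only hook.

## Gene-level aggregation

Gene intervals follow the BED convention (0-based, half-open); probe
positions are 1-based and converted internally, so a probe at 1-based
position p belongs to gene [start, end) iff start <= p − 1 < end.
Chromosome names are matched after normalizing an optional "chr" prefix.
A probe inside several (overlapping) genes counts in all of them — the
double-counting is logged so users can audit it. Gene methylation is the
unweighted mean Beta over member probes surviving QC; genes with no
surviving probes are dropped and logged. No promoter extension is applied:
the intervals provided are the unit of analysis (gene-body methylation).

## Gene selection

The outcome is regressed on the gene × sample methylation matrix with an L1
penalty (objective (1/2n)||y − b0 − Xb||² + λ||b||₁, predictors
standardized internally, coefficients reported on the original scale). The
penalty grid has 100 log-spaced points from λ_max (smallest penalty with an
all-zero solution) down to 1e-3 λ_max; λ is chosen at the minimum of the
K-fold (K = 10) cross-validated MSE, taking the LARGEST λ on ties. The
solver is scikit-learn's cyclic coordinate descent with warm starts; CV
fold assignment is the only stochastic element.

A fit is a valid **"check mark"** when (a) the CV minimum is interior to
the grid, (b) at least one predictor is selected there, and (c) the minimum
improves on the empty-model MSE by more than one CV standard error. The
analysis repeats with fresh fold seeds (base_seed + attempt) until 10 valid
fits are collected (default cap: 30 attempts; fewer than 10 valid fits is a
reported failure — on small cohorts some outcomes genuinely carry no
recoverable signal). The **consensus set** contains genes selected in >= q
of the 10 valid runs (q = 6 default, configurable; per-run sets are always
emitted so users can re-threshold); the **chosen run** is the valid run
whose selection overlaps the consensus most, ties broken by lower CV MSE.

Selection at the CV-MSE minimum is deliberately liberal — see
`docs/calibration.md` for measured sensitivity/false-positive behavior and
an independent glmnet cross-check. The de-biasing device is the
**post-selection OLS** refit on the consensus genes: joint coefficients and
p-values, adjusted R², and per-gene marginal regressions. In calibration
runs the planted genes separate from false positives by ~18 orders of
magnitude in the post-OLS p-values. Collinear columns are dropped (pivoted
QR) with a warning. Marginal p-values carry an optional Benjamini–Hochberg
column, clearly an extension: the primary report is raw p-values.

**Covariate screening** runs the same CV LASSO on the non-methylation
covariates (binary as 0/1, unordered categoricals one-hot with first level
dropped); covariates whose modal value exceeds 95% of the cohort are
excluded up front (e.g. a single smoker in 48 children).

**Site-level re-analysis** reruns the consensus selection on the member
CpGs of the consensus genes, reports which sites drive each gene, and flags
genes with no individually selected site (gene-wide mean signal).

## Methylation risk scores

For m selected genes with post-OLS coefficients w and gene methylation c,

    MRS_j = sum_i w_i c_ij .

The post-OLS intercept is stored as metadata but excluded from the score;
the association regression (outcome on score) re-estimates an intercept, so
results are invariant to this. In-sample, the score equals the joint fit's
fitted value minus its intercept, so the association R² equals the joint
R² exactly; `associate` takes a `df_model` argument so the adjusted R²
charges the honest m fitted weights in-sample (making the identity exact in
adjusted terms too) while frozen-weight transfer uses df_model = 1 (the
score is then a single pre-specified predictor). Transfer to an external
cohort never refits weights (the model hash is unchanged); gene mismatch
fails loudly unless a subset is explicitly allowed, and per-gene marginal
plus joint regressions accompany the score association.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions the tests exercise.

- **Methylation.** Per-probe mean Betas are drawn from a 3-state beta
  mixture — shared shapes (1.5, 18), (5, 5), (12, 3); weights
  (0.60, 0.10, 0.30) for cord blood (strong hypomethylated peak, smaller
  hypermethylated peak) and (0.42, 0.33, 0.25) for placenta (inflated
  intermediate mass, emulating its partial methylation). Between-sample
  variation is logit-normal: a gene-level sample effect (SD 0.35, shared by
  a gene's CpGs so gene means keep variance) plus probe-level noise
  (SD 0.25). The placenta's partial methylation is modeled as a single
  intermediate mixture state — no claim of biological fidelity (cell-type
  mixtures and hemimethylation are not distinguished).
- **Infinium II compression.** Type II probes (default 84% of the array)
  report beta' with logit(beta') = 0.7 logit(beta) — a fixed, invertible
  logit-scale shrinkage toward 0.5 reproducing the II-vs-I dynamic-range
  difference BMIQ corrects.
- **Intensities.** Signal totals S = M + U are lognormal (median 3000,
  sigma 0.35), floored at 200 and at 100·beta/(1 − beta) + 50 so that
  M = beta (S + 100), U = S − M are nonnegative and the Beta formula
  recovers beta exactly (to float precision). A configurable fraction
  (default 1%) of probes "fail": both channels uniform in (1, 40) in every
  sample, to give the background filter real work.
- **Annotation.** Disjoint genes tiled over chr1–22 with CpG counts from a
  rounded lognormal (median 7, sigma 1.23; mean ~15, min 1, right-skewed —
  at 20k genes the maximum reaches several hundred); ~4% of genes on chrX
  (sex_chrom flag), 2% of probes SNP-flagged, 2% intergenic orphan probes.
- **Phenotypes.** The latent six-month outcome is
  sum_g effect_g · z(geneBeta_g) + noise, with noise SD 0.5 so the planted
  signal explains ~80–85% of latent variance — the regime matching the high
  in-sample fits this kind of small-cohort analysis reports. The latent
  enters the six-month WAZ (coefficient 0.9 on its z-score, residual noise
  SD 0.15), from which raw weights are built; all three derived outcomes
  therefore correlate with it. Sex is Bernoulli (56% female); males weigh
  0.12 kg more at birth and 0.6 kg more at six months (WHO growth-standard
  medians: boys ~7.9 kg, girls ~7.3 kg at six months), planting the sex
  association the covariate screen should find. All other covariates
  (maternal BMI/age/health, gestational length, delivery mode, feeding mode
  at 4/16/28 weeks) are drawn independently of methylation with realistic
  cohort frequencies. Causal genes are drawn from autosomal genes with
  QC-surviving probes, or pinned by id (to give an external cohort the same
  causal structure); an optional `causal_cpg_fraction` restricts the effect
  to a random subset of a gene's CpGs to exercise the site-level follow-up.
- **Determinism.** Identical config (including seed) gives bit-identical
  cohorts; the anthropometrics use a sub-seed so methylation is unchanged
  when only phenotype settings vary.

What passing tests on this generator do **not** show about real arrays:
no batch/chip effects, no control probes or dye bias, no cell-type
composition beyond the intermediate state, no correlated neighboring genes,
and phenotype noise is Gaussian by construction. Results on synthetic data
validate the machinery, not effect sizes in any real cohort.

## Problem sizes and runtime choices

Test and reproduction runs use deliberately modest sizes chosen to exercise
each property at the smallest scale where it is meaningful: recovery at
n = 200 × 500 genes over 10 seeds, BMIQ properties at ~17k probes × 48
samples, the orchestration demo at 120 genes × 48 samples × 2 tissues, and
200 external cohorts for the transfer null. Mixture fits subsample to 8000
values; the full-data LASSO path is computed once per consensus (only fold
seeds vary across repeats).

## Known limitations

- The background filter is intensity-threshold based, not detection-p-value
  based; within-array background correction and control-probe normalization
  are out of scope (the generator produces post-correction intensities).
- `lambda_min` over-selects by design of the CV-MSE rule (see
  docs/calibration.md); downstream interpretation should lean on the
  post-OLS p-values and the consensus frequencies, both always emitted.
- Post-selection inference is plain OLS; no selective-inference correction.
- Growth-reference (WHO/LMS) z-score computation is not reimplemented.
- Multi-gene probes are double-counted by design and logged.
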
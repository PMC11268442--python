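# Calibration log

Measurements used to freeze the thresholds asserted in the test suite.
All runs use the synthetic generator defaults (noise SD 0.5, Infinium II
logit compression 0.7, CpG-per-gene law lognormal median 7 / sigma 1.23)
and the selection defaults (K = 10 folds, 100-point lambda grid down to
1e-3 of lambda_max, consensus threshold q = 6/10, penalty at the
CV-MSE-minimizing lambda, largest lambda on ties).

## Planted-signal recovery (n = 200 children, 500 genes, 5 causal, |effect| = 0.5)

Outcome: conditional weight gain z-score. Ten data seeds (1000–1009), one
consensus selection each:

| data seed | sensitivity | false positives | consensus size |
|----------:|------------:|----------------:|---------------:|
| 1000 | 1.0 |  7 | 12 |
| 1001 | 1.0 | 34 | 39 |
| 1002 | 1.0 | 37 | 42 |
| 1003 | 1.0 |  7 | 12 |
| 1004 | 1.0 | 15 | 20 |
| 1005 | 1.0 | 15 | 20 |
| 1006 | 1.0 | 56 | 61 |
| 1007 | 1.0 | 30 | 35 |
| 1008 | 1.0 | 49 | 54 |
| 1009 | 1.0 | 45 | 50 |

Mean sensitivity 1.0; mean false positives 29.5 (range 7–56).

**Independent cross-check.** The same gene tables and outcomes were exported
and fitted with R `glmnet::cv.glmnet` (nfolds = 10, nlambda = 100,
lambda.min.ratio = 1e-3). At `lambda.min`, glmnet selects 10–12 genes
(5–7 false positives) on the seed-1000 data and 41–64 genes (36–59 false
positives) on the seed-1006 data — the same range as this implementation.
Over-selection at the CV-MSE-minimizing penalty is intrinsic to that rule,
not a solver artifact: the CV curve's minimum lies deep in the path whenever
the planted coefficients are strong, because the shrinkage bias on true
coefficients dominates the cost of admitting noise genes. (At glmnet's
`lambda.1se` the same fits select exactly the 5 causal genes with 0 false
positives, but the penalty used throughout this package is the CV-MSE
minimizer, and the post-selection OLS p-values are the de-biasing device:
in the runs above the causal genes sit at p ~ 1e-20 or smaller while false
positives sit near p ~ 1e-2.)

Frozen test assertions: mean sensitivity >= 0.8 (measured 1.0); the
false-positive bound (<= 3 per run) is asserted as stated and currently
fails — the measured floor under these conditions is 7.

## Null covariate screen (n = 48, ~11 covariates after near-constant drop)

Pure-noise outcomes over 30 seeds: empty selection in 19/30 (63%).
R `glmnet` on the identical covariate matrix: 19/30. Frozen assertion:
empty selection in a majority of the fixed test seeds.

## Sex detection in BMI screen (n = 48, 10 data seeds)

With the 0.6 kg male-female weight difference at six months, `sex` is
among the selected covariates for (unstandardized) BMI in 8/10 seeds,
usually together with a few liberally-selected extras. Frozen assertion:
sex selected in >= 8/10 of the fixed seeds; membership, not set equality.

## Null consensus (n = 60, 100 genes, no planted effects, 7 seeds)

All 7 seeds ended with fewer than 10 check-mark CV curves within 20
attempts ("insufficient valid runs"). Frozen assertion: a majority of
seeds fail validity or return an empty consensus.

## Frozen-weight transfer nulls (200 external cohorts, n = 40)

Slope p-values of the MRS-outcome regression on cohorts whose outcome is
independent of methylation: Kolmogorov-Smirnov test against Uniform(0,1)
gives p = 0.60 (statistic 0.053). Frozen assertion: KS p > 0.01.
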
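"""Derive the three weight outcomes from raw anthropometrics.

Conditional weight gain (CWG) z-scores are standardized residuals of the
six-month weight-for-age z-score on its birth value (length-for-age at both
ages and exact age as covariates): mean 0, SD 1 by construction, positive =
faster-than-expected gain.  BMI and weight-for-length are standardized by
sex so downstream gene selection is not driven by sex differences.
"""

from methylgrowth import (CohortConfig, derive_outcomes, normality_report,
                          simulate_cohort)

cohort = simulate_cohort(CohortConfig(n_samples=48, n_genes=50, seed=3))
out = derive_outcomes(cohort.phenotypes)

print(out.round(3).head(8))
print(f"\nCWG:  mean = {out.cwg_z.mean():+.2e}  SD = {out.cwg_z.std(ddof=1):.6f}")
print(f"BMI:  cohort mean = {out.bmi_6m.mean():.1f} kg/m^2  "
      f"(SD {out.bmi_6m.std(ddof=1):.1f})")
print(f"WFL:  cohort mean = {out.wfl_6m.mean():.1f} kg/m   "
      f"(SD {out.wfl_6m.std(ddof=1):.1f})")
print("\nShapiro-Wilk normality (report only):")
print(normality_report(out[["cwg_z", "bmi_6m", "wfl_6m"]]).round(3))
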
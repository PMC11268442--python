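"""Infant weight outcomes: conditional weight gain, BMI, weight-for-length.

Conditional weight gain (CWG) z-scores are the standardized residuals of an
OLS regression of the six-month weight-for-age z-score on the birth
weight-for-age z-score, with length-for-age z-scores at both ages and the
exact age at the six-month visit as covariates.  By construction they have
sample mean 0 and sample SD 1 (n-1 convention) and already account for sex;
BMI and weight-for-length are standardized by sex separately.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

CWG_PREDICTORS = ["waz_birth", "laz_birth", "laz_6m", "age_6m_days"]

_Z_COLUMNS = {
    "waz_birth": "weight_birth",
    "waz_6m": "weight_6m",
    "laz_birth": "length_birth",
    "laz_6m": "length_6m",
}


def compute_bmi_wfl(records: pd.DataFrame) -> pd.DataFrame:
    """Six-month BMI (kg/m^2) and weight-for-length (kg/m).

    Lengths are given in cm and converted to m internally.  Implausible
    values (weight <= 0, outside broad infant ranges) are flagged with a
    warning but still computed.
    """
    if (records["length_6m"] <= 0).any():
        raise ValueError("nonpositive length_6m")
    length_m = records["length_6m"] / 100.0
    bmi = records["weight_6m"] / length_m**2
    wfl = records["weight_6m"] / length_m
    implausible = (records["weight_6m"] <= 0) | (bmi < 8) | (bmi > 30)
    if implausible.any():
        logger.warning("implausible anthropometrics for %d children",
                       int(implausible.sum()))
    return pd.DataFrame({"bmi_6m": bmi, "wfl_6m": wfl}, index=records.index)


def ensure_z_scores(records: pd.DataFrame) -> pd.DataFrame:
    """Pass through waz/laz columns; derive them within-sample if absent.

    External growth-reference z-scores (e.g. WHO) are preferred and are used
    verbatim when present.  When a column is missing, the corresponding raw
    measure is z-standardized within the sample at that age point, which
    preserves the regression structure downstream but is NOT a
    reference-based z-score — a loud log message marks the fallback.
    """
    out = records.copy()
    for zcol, raw in _Z_COLUMNS.items():
        if zcol not in out.columns or out[zcol].isna().all():
            vals = out[raw].astype(float)
            sd = vals.std(ddof=1)
            if sd == 0:
                raise ValueError(f"cannot derive {zcol}: {raw} is constant")
            out[zcol] = (vals - vals.mean()) / sd
            logger.warning(
                "column %s absent: falling back to within-sample "
                "z-standardization of %s (not a growth-reference z-score)",
                zcol, raw)
    return out


def conditional_weight_gain(records: pd.DataFrame) -> pd.Series:
    """CWG z-score per child: standardized residuals of waz_6m ~ predictors.

    Output has sample mean 0 and sample SD 1 (ddof=1) over the cohort it is
    computed on.
    """
    records = ensure_z_scores(records)
    n = len(records)
    if n < 7:
        raise ValueError(f"need at least 7 children for CWG, got {n}")
    X = records[CWG_PREDICTORS].astype(float)
    for col in CWG_PREDICTORS:
        if X[col].std(ddof=0) == 0:
            raise ValueError(f"rank-deficient design: column {col!r} is constant")
    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design.values)
    if rank < design.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        col = corr.max().idxmax()
        raise ValueError(f"rank-deficient design: column {col!r} is collinear")
    fit = sm.OLS(records["waz_6m"].astype(float), design).fit()
    resid = fit.resid
    sd = resid.std(ddof=1)
    if sd < 1e-12:
        raise ValueError("zero residual variance: waz_6m is an exact linear "
                         "function of the predictors")
    cwg = resid / sd
    cwg.name = "cwg_z"
    return cwg


def sex_standardize(values: pd.Series, sex: pd.Series) -> pd.Series:
    """Z-standardize within each sex (sample SD, ddof=1); original order kept."""
    values = pd.Series(values).astype(float)
    sex = pd.Series(sex).reindex(values.index)
    out = pd.Series(index=values.index, dtype=float, name=values.name)
    for level, grp in values.groupby(sex):
        if len(grp) < 2:
            raise ValueError(f"sex group {level!r} has fewer than 2 members")
        sd = grp.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero variance in sex group {level!r}")
        out.loc[grp.index] = (grp - grp.mean()) / sd
    return out


def normality_report(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Shapiro-Wilk normality p-values per outcome column (report only)."""
    rows = []
    for col in outcomes.columns:
        vals = outcomes[col].dropna()
        stat, p = stats.shapiro(vals)
        rows.append({"outcome": col, "shapiro_w": stat, "p_value": p})
    return pd.DataFrame(rows).set_index("outcome")


def derive_outcomes(records: pd.DataFrame) -> pd.DataFrame:
    """Full outcome table: cwg_z, bmi_6m, wfl_6m and sex-standardized versions."""
    bw = compute_bmi_wfl(records)
    cwg = conditional_weight_gain(records)
    out = pd.DataFrame({
        "cwg_z": cwg,
        "bmi_6m": bw["bmi_6m"],
        "wfl_6m": bw["wfl_6m"],
        "bmi_6m_sexstd": sex_standardize(bw["bmi_6m"], records["sex"]),
        "wfl_6m_sexstd": sex_standardize(bw["wfl_6m"], records["sex"]),
    })
    return out
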
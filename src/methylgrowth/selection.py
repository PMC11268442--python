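"""Gene selection by cross-validated LASSO with a repeated-run consensus.

The selection procedure mirrors a common EWAS workflow on small cohorts:
an L1-penalized regression of the weight outcome on gene-level methylation,
with the penalty chosen by K-fold cross-validation at the minimum of the
CV mean-squared-error curve.  Because fold assignment is the only random
element, the CV curve (and hence the selected gene set) varies from run to
run; a fit is accepted only when its CV curve has the "check mark" shape —
an interior minimum, at least one selected predictor, and a minimum clearly
below the MSE of the empty model.  The analysis is repeated until ten valid
fits are collected, genes are ranked by how often they were selected, and
the consensus set (selected in >= q of 10 runs, default q = 6) feeds a
post-selection OLS refit that de-biases the coefficients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class InsufficientValidRunsError(RuntimeError):
    """Raised when fewer than the target number of check-mark fits appear."""

    def __init__(self, n_valid: int, n_target: int, max_attempts: int):
        self.n_valid = n_valid
        super().__init__(
            f"insufficient valid runs: {n_valid}/{n_target} check-mark fits "
            f"within {max_attempts} attempts")


# ---------------------------------------------------------------------------
# cross-validated lasso


@dataclass
class LassoFit:
    """One cross-validated L1 path.

    Coefficients are reported on the original predictor scale;
    ``coef_path_std`` keeps the standardized-scale path for optimality
    (KKT) verification.
    """

    lambdas: np.ndarray
    coef_path: np.ndarray        # p x L, original scale
    intercept_path: np.ndarray   # L
    coef_path_std: np.ndarray    # p x L, standardized scale
    cv_mse: np.ndarray
    cv_se: np.ndarray
    idx_min: int
    feature_names: list[str]
    seed: int
    standardized: bool
    x_mean: np.ndarray
    x_scale: np.ndarray
    dropped: list[str] = field(default_factory=list)

    @property
    def lambda_min(self) -> float:
        return float(self.lambdas[self.idx_min])

    @property
    def coef_min(self) -> pd.Series:
        return pd.Series(self.coef_path[:, self.idx_min],
                         index=self.feature_names, name="coef")

    @property
    def intercept_min(self) -> float:
        return float(self.intercept_path[self.idx_min])

    @property
    def selected(self) -> list[str]:
        c = self.coef_path[:, self.idx_min]
        return [n for n, v in zip(self.feature_names, c) if v != 0.0]

    @property
    def cv_mse_min(self) -> float:
        return float(self.cv_mse[self.idx_min])


def _prepare(X: pd.DataFrame, y: pd.Series, standardize: bool):
    Xv = X.values.astype(float)
    yv = np.asarray(y, dtype=float)
    if np.isnan(Xv).any() or np.isnan(yv).any():
        raise ValueError("NaNs in predictors or outcome")
    sd = Xv.std(axis=0)  # population convention, as in glmnet
    keep = sd > 0
    dropped = [n for n, k in zip(X.columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance predictors: {dropped[:5]}"
                      + ("..." if len(dropped) > 5 else ""))
        Xv, sd = Xv[:, keep], sd[keep]
    names = [n for n, k in zip(X.columns, keep) if k]
    mean = Xv.mean(axis=0)
    scale = sd if standardize else np.ones_like(sd)
    Xs = (Xv - mean) / scale
    return Xs, yv, names, mean, scale, dropped


def cv_lasso(X: pd.DataFrame, y: pd.Series, k_folds: int = 10,
             n_lambdas: int = 100, lambda_min_ratio: float = 1e-3,
             seed: int = 0, standardize: bool = True,
             solver_tol: float = 1e-4,
             full_path: np.ndarray | None = None) -> LassoFit:
    """K-fold cross-validated LASSO along a log-spaced penalty grid.

    The objective is the glmnet/scikit-learn convention
    ``(1/2n)||y - b0 - X b||^2 + lambda ||b||_1``.  The grid runs from
    ``lambda_max`` (smallest penalty with an all-zero solution) down by
    ``lambda_min_ratio``; ``lambda_min`` is the LARGEST penalty attaining
    the minimum CV MSE (ties resolved toward the sparser model).
    X is samples x predictors.

    ``full_path`` lets callers that refit the same data repeatedly (only the
    fold seed changes) reuse the standardized full-data coefficient path.
    """
    n = len(X)
    if not 3 <= k_folds <= n:
        raise ValueError(f"need n >= K >= 3, got n={n}, K={k_folds}")
    if np.std(np.asarray(y, dtype=float)) == 0:
        raise ValueError("zero-variance outcome")
    Xs, yv, names, mean, scale, dropped = _prepare(X, y, standardize)
    yc = yv - yv.mean()

    lambda_max = np.max(np.abs(Xs.T @ yc)) / n
    lambdas = np.geomspace(lambda_max, lambda_max * lambda_min_ratio, n_lambdas)

    folds = list(KFold(n_splits=k_folds, shuffle=True,
                       random_state=seed).split(Xs))
    fold_mse = np.empty((k_folds, n_lambdas))
    with warnings.catch_warnings():
        # loose duality-gap stops on noisy CV folds are expected and harmless
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        for f, (tr, te) in enumerate(folds):
            Xtr = Xs[tr] - Xs[tr].mean(axis=0)
            ytr = yv[tr] - yv[tr].mean()
            _, coefs, _ = lasso_path(Xtr, ytr, alphas=lambdas, tol=solver_tol)
            pred = ((Xs[te] - Xs[tr].mean(axis=0)) @ coefs) + yv[tr].mean()
            fold_mse[f] = ((yv[te, None] - pred) ** 2).mean(axis=0)
        cv_mse = fold_mse.mean(axis=0)
        cv_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(k_folds)

        if full_path is None:
            _, coefs_std, _ = lasso_path(Xs, yc, alphas=lambdas,
                                         tol=solver_tol)
        else:
            coefs_std = full_path
    coef_orig = coefs_std / scale[:, None]
    intercepts = yv.mean() - mean @ coef_orig

    # largest lambda achieving the minimum (grid is decreasing)
    idx_min = int(np.argmin(cv_mse))
    return LassoFit(lambdas=lambdas, coef_path=coef_orig,
                    intercept_path=intercepts, coef_path_std=coefs_std,
                    cv_mse=cv_mse, cv_se=cv_se, idx_min=idx_min,
                    feature_names=names, seed=seed, standardized=standardize,
                    x_mean=mean, x_scale=scale, dropped=dropped)


def checkmark_valid(fit: LassoFit) -> bool:
    """Operational "check mark" rule for a CV curve.

    True iff (a) the CV minimum is interior to the lambda grid, (b) at least
    one predictor is selected there, and (c) the minimum improves on the
    empty-model MSE (at lambda_max) by more than one CV standard error.
    """
    interior = 0 < fit.idx_min < len(fit.lambdas) - 1
    nonempty = len(fit.selected) >= 1
    improves = (fit.cv_mse[0] - fit.cv_mse[fit.idx_min]) > fit.cv_se[fit.idx_min]
    return bool(interior and nonempty and improves)


# ---------------------------------------------------------------------------
# consensus over repeated runs


@dataclass
class ConsensusResult:
    runs: list[LassoFit]             # the valid (check-mark) runs
    n_attempts: int
    frequencies: pd.Series           # per gene, over valid runs
    consensus: list[str]             # selected in >= q of the valid runs
    chosen_run: int                  # index into runs
    q: int
    base_seed: int

    @property
    def n_valid_runs(self) -> int:
        return len(self.runs)

    @property
    def per_run_selected(self) -> list[list[str]]:
        return [r.selected for r in self.runs]

    def report(self) -> dict:
        return {
            "n_valid_runs": self.n_valid_runs,
            "n_attempts": self.n_attempts,
            "q": self.q,
            "base_seed": self.base_seed,
            "per_run": [{"seed": r.seed, "selected": r.selected,
                         "cv_mse_min": r.cv_mse_min} for r in self.runs],
            "frequencies": self.frequencies.to_dict(),
            "consensus": self.consensus,
            "chosen_run_seed": self.runs[self.chosen_run].seed,
        }


def consensus_select(X: pd.DataFrame, y: pd.Series, k_folds: int = 10,
                     n_target_valid: int = 10, max_attempts: int = 30,
                     q: int = 6, base_seed: int = 0,
                     **lasso_kwargs) -> ConsensusResult:
    """Repeat cv_lasso with fresh fold seeds until 10 check-mark fits.

    Fold seeds are ``base_seed + attempt``.  The consensus set contains
    genes selected in at least ``q`` of the valid runs; the chosen run is
    the valid run whose selected set overlaps the consensus most (ties
    resolved by lower CV MSE at lambda_min).
    """
    if max_attempts < n_target_valid:
        raise ValueError("max_attempts must be >= n_target_valid")
    valid: list[LassoFit] = []
    attempt = 0
    full_path = None
    while attempt < max_attempts and len(valid) < n_target_valid:
        fit = cv_lasso(X, y, k_folds=k_folds, seed=base_seed + attempt,
                       full_path=full_path, **lasso_kwargs)
        full_path = fit.coef_path_std  # identical across fold seeds

        if checkmark_valid(fit):
            valid.append(fit)
        attempt += 1
    if len(valid) < n_target_valid:
        raise InsufficientValidRunsError(len(valid), n_target_valid, max_attempts)

    counts: dict[str, int] = {}
    for fit in valid:
        for g in fit.selected:
            counts[g] = counts.get(g, 0) + 1
    freq = pd.Series(counts, dtype=int).sort_values(ascending=False)
    consensus = sorted(freq.index[freq >= q])

    def key(i: int):
        overlap = len(set(valid[i].selected) & set(consensus))
        return (-overlap, valid[i].cv_mse_min)

    chosen = min(range(len(valid)), key=key)
    return ConsensusResult(runs=valid, n_attempts=attempt, frequencies=freq,
                           consensus=consensus, chosen_run=chosen, q=q,
                           base_seed=base_seed)


# ---------------------------------------------------------------------------
# post-selection fits


@dataclass
class PostFitResult:
    coefficients: pd.Series      # includes "const"
    p_values: pd.Series
    adj_r2: float
    r2: float
    marginal: pd.DataFrame       # per predictor: coef, p_value, r2, p_value_bh
    n: int
    dropped_collinear: list[str] = field(default_factory=list)


def post_selection_ols(X: pd.DataFrame, y: pd.Series,
                       predictors: list[str] | None = None) -> PostFitResult:
    """OLS refit on the selected predictors, plus marginal regressions.

    Collinear columns are dropped (QR with pivoting) with a warning.  The
    Benjamini-Hochberg column on the marginal p-values is an extension
    beyond plain reporting and is clearly labeled as such.
    """
    cols = list(predictors) if predictors is not None else list(X.columns)
    if not cols:
        raise ValueError("empty predictor set for post-selection OLS")
    n = len(X)
    if len(cols) >= n - 1:
        raise ValueError(f"too many predictors ({len(cols)}) for n={n}")
    Xsel = X[cols].astype(float)

    dropped = []
    rank = np.linalg.matrix_rank(sm.add_constant(Xsel).values)
    if rank < len(cols) + 1:
        _, _, piv = qr(Xsel.values - Xsel.values.mean(axis=0), pivoting=True)
        keep_n = rank - 1
        keep = sorted(piv[:keep_n])
        dropped = [cols[i] for i in range(len(cols)) if i not in keep]
        warnings.warn(f"dropping collinear predictors: {dropped}")
        cols = [cols[i] for i in keep]
        Xsel = Xsel[cols]
        if not cols:
            raise ValueError("rank-deficient design after drops")

    yv = pd.Series(y).astype(float)
    fit = sm.OLS(yv, sm.add_constant(Xsel)).fit()

    rows = []
    for c in cols:
        mfit = sm.OLS(yv, sm.add_constant(Xsel[[c]])).fit()
        rows.append({"predictor": c, "coef": mfit.params[c],
                     "p_value": mfit.pvalues[c], "r2": mfit.rsquared})
    marginal = pd.DataFrame(rows).set_index("predictor")
    marginal["p_value_bh"] = multipletests(marginal["p_value"],
                                           method="fdr_bh")[1]

    return PostFitResult(coefficients=fit.params, p_values=fit.pvalues,
                         adj_r2=float(fit.rsquared_adj), r2=float(fit.rsquared),
                         marginal=marginal, n=n, dropped_collinear=dropped)


# ---------------------------------------------------------------------------
# covariate screening


def screen_covariates(covariates: pd.DataFrame, outcome: pd.Series,
                      seed: int = 0, k_folds: int = 10,
                      near_constant_threshold: float = 0.95) -> dict:
    """LASSO screen of non-methylation covariates against a weight outcome.

    Unordered categorical covariates are one-hot encoded (first level
    dropped); covariates whose modal value exceeds ``near_constant_threshold``
    of the cohort are excluded up front with a log entry.  Returns the
    covariates with nonzero coefficient at lambda_min.
    """
    enc = pd.get_dummies(covariates, drop_first=True).astype(float)
    near_const = [c for c in enc.columns
                  if enc[c].value_counts(normalize=True).iloc[0]
                  > near_constant_threshold]
    if near_const:
        logger.info("screen_covariates: dropping near-constant %s", near_const)
        enc = enc.drop(columns=near_const)
    fit = cv_lasso(enc, outcome, k_folds=k_folds, seed=seed)
    return {"selected": fit.selected, "fit": fit, "dropped_near_constant": near_const}


# ---------------------------------------------------------------------------
# CpG-site-level re-analysis


def site_level_reanalysis(betas: pd.DataFrame, membership: dict[str, list[str]],
                          consensus_genes: list[str], y: pd.Series,
                          base_seed: int = 0, **consensus_kwargs) -> dict:
    """Rerun consensus selection on the member CpGs of the consensus genes.

    Reports which sites drive each gene's association and flags genes with
    no individually selected CpG (where the gene-wide mean, not specific
    sites, carries the signal).
    """
    if not consensus_genes:
        raise ValueError("no consensus genes for site-level re-analysis")
    site_gene = {}
    sites = []
    for g in consensus_genes:
        for p in membership[g]:
            if p in betas.index:
                site_gene[p] = g
                sites.append(p)
    Xsites = betas.loc[sites].T  # samples x sites
    result = consensus_select(Xsites, y, base_seed=base_seed, **consensus_kwargs)
    per_gene = {g: [s for s in result.consensus if site_gene[s] == g]
                for g in consensus_genes}
    return {
        "consensus_sites": result.consensus,
        "per_gene_sites": per_gene,
        "genes_without_sites": [g for g, s in per_gene.items() if not s],
        "result": result,
        "site_gene": site_gene,
    }
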
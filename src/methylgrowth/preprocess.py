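"""Intensity-to-Beta conversion, probe/sample QC, and BMIQ normalization.

Methylation arrays report two fluorescence intensities per CpG probe:
methylated (M) and unmethylated (U).  The methylation level is summarized
as the Beta value ``beta = M / (M + U + 100)``; the +100 offset regularizes
low-intensity probes.  Infinium I and Infinium II probe chemistries have
different dynamic ranges, so Beta values from the two designs are not
directly comparable.  BMIQ (beta-mixture quantile normalization) fits a
three-state beta mixture (unmethylated / hemimethylated / methylated) to
each design within a sample and maps the type II state distributions onto
the type I ones, leaving type I probes untouched.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

BETA_OFFSET = 100.0
_EPS = 1e-6


# ---------------------------------------------------------------------------
# containers


@dataclass
class IntensityMatrix:
    """Methylated/unmethylated signal intensities, probes x samples."""

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.methylated.index.equals(self.unmethylated.index):
            raise ValueError("methylated/unmethylated probe ids differ")
        if not self.methylated.columns.equals(self.unmethylated.columns):
            raise ValueError("methylated/unmethylated sample ids differ")
        if self.methylated.index.has_duplicates:
            raise ValueError("duplicate probe ids in intensity matrix")
        for name, df in (("methylated", self.methylated),
                         ("unmethylated", self.unmethylated)):
            if (df.values < 0).any():
                probe, sample = _first_negative(df)
                raise ValueError(
                    f"negative {name} intensity at probe {probe!r}, "
                    f"sample {sample!r}"
                )

    @property
    def probes(self) -> pd.Index:
        return self.methylated.index

    @property
    def samples(self) -> pd.Index:
        return self.methylated.columns

    def total(self) -> pd.DataFrame:
        return self.methylated + self.unmethylated

    def subset(self, probes=None, samples=None) -> "IntensityMatrix":
        m, u = self.methylated, self.unmethylated
        if probes is not None:
            m, u = m.loc[probes], u.loc[probes]
        if samples is not None:
            m, u = m[samples], u[samples]
        return IntensityMatrix(m, u)


@dataclass
class BetaMatrix:
    """Beta values in [0, 1], probes x samples, with annotation and a QC log.

    ``qc_log`` records one entry per filtering/normalization stage with the
    number of probes/samples going in and out so the bookkeeping can be
    reconciled (probes_in - removed == probes_out at each stage).
    """

    beta: pd.DataFrame
    annotation: pd.DataFrame | None = None
    qc_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.beta.values
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("Beta values outside [0, 1]")

    @property
    def probes(self) -> pd.Index:
        return self.beta.index

    @property
    def samples(self) -> pd.Index:
        return self.beta.columns

    def log_stage(self, stage: str, *, probes_removed: int = 0,
                  samples_removed: int = 0, detail: dict | None = None) -> None:
        self.qc_log.append({
            "stage": stage,
            "probes_in": len(self.beta.index) + probes_removed,
            "probes_removed": probes_removed,
            "probes_out": len(self.beta.index),
            "samples_removed": samples_removed,
            **(detail or {}),
        })


# ---------------------------------------------------------------------------
# Beta computation and filters


def compute_beta(methylated, unmethylated, offset: float = BETA_OFFSET):
    """Beta value M / (M + U + offset), elementwise.

    Accepts scalars, arrays, or DataFrames.  Raises on negative input,
    naming the offending probe/sample where index information is available.
    """
    if isinstance(methylated, pd.DataFrame):
        for name, df in (("methylated", methylated), ("unmethylated", unmethylated)):
            if (df.values < 0).any():
                probe, sample = _first_negative(df)
                raise ValueError(
                    f"negative {name} intensity at probe {probe!r}, sample {sample!r}"
                )
        out = methylated / (methylated + unmethylated + offset)
        return out
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("negative intensity passed to compute_beta")
    return m / (m + u + offset)


def intensities_to_beta(intensities: IntensityMatrix,
                        annotation: pd.DataFrame | None = None) -> BetaMatrix:
    beta = compute_beta(intensities.methylated, intensities.unmethylated)
    bm = BetaMatrix(beta, annotation=annotation)
    bm.log_stage("compute_beta")
    return bm


def background_filter(intensities: IntensityMatrix, background_threshold: float,
                      min_fraction: float = 1.0) -> pd.Series:
    """Flag probes whose M and U are both below background.

    A probe is flagged for removal when, in at least ``min_fraction`` of
    samples, BOTH channels are strictly below ``background_threshold``.
    Returns a boolean Series (True = remove) indexed by probe.
    """
    if background_threshold <= 0:
        raise ValueError("background_threshold must be > 0")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    low = ((intensities.methylated.values < background_threshold)
           & (intensities.unmethylated.values < background_threshold))
    frac_low = low.mean(axis=1)
    remove = pd.Series(frac_low >= min_fraction, index=intensities.probes,
                       name="background_fail")
    logger.info("background_filter: %d/%d probes below background",
                int(remove.sum()), len(remove))
    return remove


def annotation_filters(betas: BetaMatrix, annotation: pd.DataFrame | None = None
                       ) -> BetaMatrix:
    """Drop probes flagged as SNP-overlapping or on a sex chromosome."""
    ann = annotation if annotation is not None else betas.annotation
    if ann is None:
        raise ValueError("no probe annotation provided")
    missing = betas.probes.difference(ann.index)
    if len(missing):
        raise KeyError(
            "probes missing from annotation: "
            + ", ".join(map(str, missing[:10]))
            + ("..." if len(missing) > 10 else "")
        )
    ann = ann.loc[betas.probes]
    snp = ann["snp_flag"].astype(bool)
    sexchrom = ann["sex_chrom_flag"].astype(bool)
    drop = snp | sexchrom
    keep = betas.probes[~drop.values]
    if len(keep) == 0:
        raise ValueError("empty matrix after filtering")
    out = BetaMatrix(betas.beta.loc[keep],
                     annotation=ann.loc[keep],
                     qc_log=list(betas.qc_log))
    out.log_stage("annotation_filters", probes_removed=int(drop.sum()),
                  detail={"snp_flagged": int(snp.sum()),
                          "sex_chrom_flagged": int(sexchrom.sum())})
    return out


def sample_outlier_screen(intensities: IntensityMatrix,
                          min_median_log_intensity: float = 10.0) -> pd.Series:
    """Flag low-quality samples by median log2 total intensity.

    Returns a boolean Series (True = remove) indexed by sample.
    """
    total = intensities.total().values
    med = np.median(np.log2(total + 1.0), axis=0)
    remove = pd.Series(med < min_median_log_intensity,
                       index=intensities.samples, name="low_quality")
    if remove.all():
        raise ValueError("all samples removed by outlier screen")
    if remove.any():
        logger.info("sample_outlier_screen: removing %s",
                    list(remove.index[remove]))
    return remove


# ---------------------------------------------------------------------------
# three-state beta mixture


@dataclass
class BetaMixtureFit:
    """EM fit of a K-state beta mixture, components ordered by mean."""

    weights: np.ndarray
    a: np.ndarray
    b: np.ndarray
    thresholds: tuple[float, ...]
    loglik: float
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool

    @property
    def means(self) -> np.ndarray:
        return self.a / (self.a + self.b)

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """Per-component log density, shape (n, K)."""
        x = np.asarray(x)[:, None]
        return ((self.a - 1) * np.log(x) + (self.b - 1) * np.log1p(-x)
                - special.betaln(self.a, self.b))

    def posterior(self, x: np.ndarray) -> np.ndarray:
        lp = self.log_density(np.asarray(x)) + np.log(self.weights)
        lp -= lp.max(axis=1, keepdims=True)
        p = np.exp(lp)
        return p / p.sum(axis=1, keepdims=True)


def _component_stats(x: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    return float(w.sum()), float(w @ np.log(x)), float(w @ np.log1p(-x))


def _fit_beta_weighted(sw: float, slx: float, sl1x: float,
                       a0: float, b0: float) -> tuple[float, float]:
    """Weighted ML beta fit from sufficient statistics, warm-started.

    Never returns parameters worse than the start, which keeps the EM
    log-likelihood monotone.
    """

    def negll(logab):
        a, b = np.exp(logab)
        return -((a - 1) * slx + (b - 1) * sl1x - sw * special.betaln(a, b))

    def grad(logab):
        a, b = np.exp(logab)
        dig_ab = special.digamma(a + b)
        da = -(slx - sw * (special.digamma(a) - dig_ab)) * a
        db = -(sl1x - sw * (special.digamma(b) - dig_ab)) * b
        return np.array([da, db])

    x0 = np.log([a0, b0])
    res = optimize.minimize(negll, x0, jac=grad, method="L-BFGS-B",
                            bounds=[(np.log(1e-2), np.log(1e4))] * 2)
    if res.fun <= negll(x0):
        a, b = np.exp(res.x)
        return float(a), float(b)
    return a0, b0


def _moment_beta(x: np.ndarray) -> tuple[float, float]:
    m = float(np.mean(x))
    v = float(np.var(x))
    m = min(max(m, 1e-3), 1 - 1e-3)
    v = min(max(v, 1e-6), m * (1 - m) * 0.99)
    k = m * (1 - m) / v - 1
    return max(m * k, 1e-2), max((1 - m) * k, 1e-2)


def fit_beta_mixture(values, n_states: int = 3, tol: float = 1e-5,
                     max_iter: int = 200, seed: int | None = None,
                     init_cuts: tuple[float, float] = (0.25, 0.75)
                     ) -> BetaMixtureFit:
    """EM for an ``n_states``-component beta mixture on values in (0, 1).

    Values are clamped to [1e-6, 1 - 1e-6].  Initialization is quantile/
    moment based at ``init_cuts``; components are relabeled by increasing
    mean.  The log-likelihood is nondecreasing across iterations.
    ``seed`` is accepted for interface stability (the default deterministic
    initialization uses no randomness).
    """
    x = np.clip(np.asarray(values, dtype=float).ravel(), _EPS, 1 - _EPS)
    if x.size < 50:
        raise ValueError(f"need >= 50 values to fit a beta mixture, got {x.size}")
    if n_states < 1:
        raise ValueError("n_states must be >= 1")

    # initialization: split at fixed cut points, moment-match each group
    if n_states == 3:
        groups = [x[x <= init_cuts[0]],
                  x[(x > init_cuts[0]) & (x < init_cuts[1])],
                  x[x >= init_cuts[1]]]
    else:
        qs = np.quantile(x, np.linspace(0, 1, n_states + 1))
        groups = [x[(x >= qs[i]) & (x <= qs[i + 1])] for i in range(n_states)]
    defaults = [(2.0, 10.0), (5.0, 5.0), (10.0, 2.0)]
    a = np.empty(n_states)
    b = np.empty(n_states)
    w = np.empty(n_states)
    for k, g in enumerate(groups):
        if g.size >= 5:
            a[k], b[k] = _moment_beta(g)
        else:
            a[k], b[k] = defaults[min(k, 2)]
        w[k] = max(g.size, 1) / x.size
    w /= w.sum()

    lx, l1x = np.log(x), np.log1p(-x)
    trace = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step
        logd = ((a - 1) * lx[:, None] + (b - 1) * l1x[:, None]
                - special.betaln(a, b) + np.log(w))
        mx = logd.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(logd - mx).sum(axis=1))
        loglik = float(lse.sum())
        trace.append(loglik)
        resp = np.exp(logd - lse[:, None])
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (1 + abs(trace[-2])):
            converged = True
            break
        # M-step
        w = resp.mean(axis=0)
        w = np.maximum(w, 1e-10)
        w /= w.sum()
        for k in range(n_states):
            sw, slx, sl1x = _component_stats(x, resp[:, k])
            if sw > 1e-8:
                a[k], b[k] = _fit_beta_weighted(sw, slx, sl1x, a[k], b[k])
    if not converged:
        warnings.warn("beta mixture EM did not converge", RuntimeWarning)

    order = np.argsort(a / (a + b))
    w, a, b = w[order], a[order], b[order]
    fit = BetaMixtureFit(weights=w, a=a, b=b, thresholds=(),
                         loglik=trace[-1], loglik_trace=np.asarray(trace),
                         n_iter=n_iter, converged=converged)
    fit.thresholds = _state_thresholds(fit)
    return fit


def _state_thresholds(fit: BetaMixtureFit) -> tuple[float, ...]:
    """Cut points in (0,1) where the maximum-posterior state changes."""
    grid = np.linspace(_EPS, 1 - _EPS, 4001)
    labels = fit.posterior(grid).argmax(axis=1)
    k = len(fit.weights)
    cuts = []
    for state in range(k - 1):
        in_low = grid[labels <= state]
        in_high = grid[labels > state]
        if in_low.size and in_high.size:
            cuts.append(float(in_low.max()))
        else:
            # degenerate fit: fall back to quantile between component means
            means = fit.means
            cuts.append(float((means[state] + means[min(state + 1, k - 1)]) / 2))
    # enforce strict ordering
    for i in range(1, len(cuts)):
        cuts[i] = max(cuts[i], cuts[i - 1] + 1e-4)
    return tuple(cuts)


# ---------------------------------------------------------------------------
# BMIQ


def _bmiq_map_sample(x2: np.ndarray, fit1: BetaMixtureFit, fit2: BetaMixtureFit
                     ) -> np.ndarray:
    """Monotone map taking type II Betas onto the type I state distributions.

    Unmethylated- and methylated-state values are quantile-mapped between
    the fitted state beta distributions; hemimethylated values get an affine
    dilation pinned to the mapped state boundaries, so the overall transform
    is strictly increasing.
    """
    t1, t2 = fit2.thresholds
    aU2, bU2 = fit2.a[0], fit2.b[0]
    aM2, bM2 = fit2.a[2], fit2.b[2]
    aU1, bU1 = fit1.a[0], fit1.b[0]
    aM1, bM1 = fit1.a[2], fit1.b[2]

    def map_u(v):
        return stats.beta.ppf(stats.beta.cdf(v, aU2, bU2), aU1, bU1)

    def map_m(v):
        return stats.beta.ppf(stats.beta.cdf(v, aM2, bM2), aM1, bM1)

    lo = float(map_u(t1))
    hi = float(map_m(t2))
    if not hi > lo:  # pathological fit; keep ordering with a minimal gap
        hi = lo + 1e-6

    out = np.empty_like(x2)
    is_u = x2 <= t1
    is_m = x2 >= t2
    is_h = ~(is_u | is_m)
    out[is_u] = map_u(x2[is_u])
    out[is_m] = map_m(x2[is_m])
    out[is_h] = lo + (x2[is_h] - t1) / (t2 - t1) * (hi - lo)
    return np.clip(out, 0.0, 1.0)


def bmiq_normalize(betas: BetaMatrix, design_type: pd.Series | None = None,
                   seed: int | None = None, max_fit_values: int = 8000
                   ) -> BetaMatrix:
    """BMIQ: rescale Infinium II Betas to the Infinium I distribution.

    Per sample, three-state beta mixtures are fitted to the type I and
    type II probes (on a random subsample of at most ``max_fit_values``
    values when larger, for speed) and type II values are transformed by a
    strictly monotone state-wise quantile map.  Type I values pass through
    bit-identical.
    """
    if design_type is None:
        if betas.annotation is None or "design_type" not in betas.annotation:
            raise ValueError("design_type required (argument or annotation)")
        design_type = betas.annotation.loc[betas.probes, "design_type"]
    design_type = design_type.loc[betas.probes]
    is_ii = (design_type.astype(str).str.upper() == "II").values
    if is_ii.all() or not is_ii.any():
        raise ValueError("BMIQ requires both Infinium I and II probes")

    rng = np.random.default_rng(seed)
    out = betas.beta.copy()
    for sample in betas.samples:
        col = betas.beta[sample].values
        x1 = np.clip(col[~is_ii], _EPS, 1 - _EPS)
        x2 = np.clip(col[is_ii], _EPS, 1 - _EPS)
        fit1 = fit_beta_mixture(_subsample(x1, max_fit_values, rng))
        fit2 = fit_beta_mixture(_subsample(x2, max_fit_values, rng))
        try:
            mapped = _bmiq_map_sample(x2, fit1, fit2)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"BMIQ failed for sample {sample!r}") from exc
        newcol = col.copy()
        newcol[is_ii] = mapped
        out[sample] = newcol
    res = BetaMatrix(out, annotation=betas.annotation, qc_log=list(betas.qc_log))
    res.log_stage("bmiq", detail={"n_samples_normalized": len(betas.samples),
                                  "n_infii_probes": int(is_ii.sum())})
    return res


def _subsample(x: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    if x.size <= n:
        return x
    return rng.choice(x, size=n, replace=False)


# ---------------------------------------------------------------------------
# end-to-end convenience


def preprocess_pipeline(intensities: IntensityMatrix, annotation: pd.DataFrame,
                        background_threshold: float = 50.0,
                        min_median_log_intensity: float = 10.0,
                        bmiq: bool = True, seed: int | None = None
                        ) -> BetaMatrix:
    """Intensities -> QC-filtered (optionally BMIQ-normalized) Beta matrix."""
    bad_samples = sample_outlier_screen(intensities, min_median_log_intensity)
    keep_samples = intensities.samples[~bad_samples.values]
    intensities = intensities.subset(samples=keep_samples)

    bg = background_filter(intensities, background_threshold)
    keep = intensities.probes[~bg.values]
    intensities = intensities.subset(probes=keep)

    betas = intensities_to_beta(intensities, annotation=annotation.loc[keep])
    betas.log_stage("background_filter", probes_removed=int(bg.sum()),
                    samples_removed=int(bad_samples.sum()))
    betas = annotation_filters(betas)
    if bmiq:
        betas = bmiq_normalize(betas, seed=seed)
    return betas


def _first_negative(df: pd.DataFrame) -> tuple:
    r, c = np.argwhere(df.values < 0)[0]
    return df.index[r], df.columns[c]
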
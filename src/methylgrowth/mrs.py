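"""Methylation Risk Scores: weighted sums of gene methylation values.

The score for child j is ``MRS_j = sum_i w_i * c_ij`` over the m selected
genes, where c_ij is the gene-level mean Beta and the weights w_i are the
de-biased post-selection OLS coefficients.  The post-OLS intercept is kept
as metadata but excluded from the score (the score definition has no
intercept; the association regression re-estimates one, so results do not
depend on this choice).  Transfer to an external cohort applies the FROZEN
weights — no refitting — and additionally reports per-gene marginal and
joint regressions of the external outcome on the model genes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genes import GeneMethylationTable
from .selection import PostFitResult, post_selection_ols


@dataclass
class MrsModel:
    outcome: str
    tissue: str
    genes: list[str]
    weights: list[float]
    intercept: float = 0.0          # metadata only, not part of the score
    source: str = "synthetic"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.genes) != len(self.weights):
            raise ValueError("genes and weights length mismatch")
        if len(self.genes) == 0:
            raise ValueError("MRS model needs at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in MRS model")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite MRS weights")

    @property
    def weight_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.genes, name="weight")

    def content_hash(self) -> str:
        payload = json.dumps({"genes": self.genes, "weights": self.weights},
                             sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "MrsModel":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class MrsAssociation:
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    p_value: float
    n: int
    scores: pd.Series


def build_mrs(postfit: PostFitResult, outcome: str, tissue: str,
              source: str = "synthetic", metadata: dict | None = None
              ) -> MrsModel:
    """Turn a post-selection OLS fit into an MRS model (weights frozen)."""
    coefs = postfit.coefficients.drop("const")
    return MrsModel(outcome=outcome, tissue=tissue,
                    genes=list(coefs.index), weights=[float(v) for v in coefs],
                    intercept=float(postfit.coefficients.get("const", 0.0)),
                    source=source, metadata=metadata or {})


def compute_mrs(gene_table: GeneMethylationTable | pd.DataFrame,
                model: MrsModel) -> pd.Series:
    """Per-child score: sum of weighted gene methylation values."""
    values = gene_table.values if isinstance(gene_table, GeneMethylationTable) \
        else gene_table
    missing = [g for g in model.genes if g not in values.index]
    if missing:
        raise KeyError(f"genes missing from methylation table: {missing}")
    sub = values.loc[model.genes]  # genes x samples
    scores = pd.Series(np.asarray(model.weights) @ sub.values,
                       index=sub.columns, name="mrs")
    return scores


def associate(scores: pd.Series, outcome: pd.Series,
              df_model: int = 1) -> MrsAssociation:
    """Simple OLS of the weight outcome on the score.

    ``df_model`` controls the adjusted-R2 penalty: when the score was built
    in-sample from m fitted gene coefficients, passing ``df_model=m`` charges
    the honest degrees of freedom and makes the in-sample adjusted R2 equal
    to the joint post-selection fit's.  For frozen-weight transfer to new
    data the score is a single pre-specified predictor (``df_model=1``).
    """
    scores = pd.Series(scores).astype(float)
    outcome = pd.Series(outcome).astype(float).reindex(scores.index)
    n = len(scores)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if scores.std(ddof=0) == 0:
        raise ValueError("zero score variance")
    fit = sm.OLS(outcome.values, sm.add_constant(scores.values)).fit()
    r2 = float(fit.rsquared)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - df_model - 1)
    return MrsAssociation(slope=float(fit.params[1]),
                          intercept=float(fit.params[0]),
                          r2=r2, adj_r2=adj,
                          p_value=float(fit.pvalues[1]), n=n, scores=scores)


def transfer(model: MrsModel, gene_table: GeneMethylationTable | pd.DataFrame,
             outcome: pd.Series, allow_subset: bool = False) -> dict:
    """Apply frozen MRS weights to an external cohort.

    Fails loudly when model genes are missing from the external table unless
    ``allow_subset`` is set (then the score uses the overlap, reported).
    Also regresses the external outcome on each model gene marginally and on
    all model genes jointly.
    """
    values = gene_table.values if isinstance(gene_table, GeneMethylationTable) \
        else gene_table
    overlap = [g for g in model.genes if g in values.index]
    if not overlap:
        raise KeyError("no overlap between model genes and external table")
    if len(overlap) < len(model.genes) and not allow_subset:
        missing = sorted(set(model.genes) - set(overlap))
        raise KeyError(f"model genes missing from external table: {missing} "
                       "(pass allow_subset=True to proceed on the overlap)")
    used = MrsModel(outcome=model.outcome, tissue=model.tissue,
                    genes=overlap,
                    weights=[float(model.weight_series[g]) for g in overlap],
                    intercept=model.intercept, source=model.source,
                    metadata=model.metadata) if len(overlap) < len(model.genes) \
        else model
    scores = compute_mrs(values, used)
    assoc = associate(scores, outcome, df_model=1)
    X = values.loc[overlap].T  # samples x genes
    joint = post_selection_ols(X, outcome.reindex(X.index), overlap)
    return {
        "association": assoc,
        "joint": joint,
        "marginal": joint.marginal,
        "gene_overlap": overlap,
        "n_model_genes": len(model.genes),
        "model_hash": model.content_hash(),
    }
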
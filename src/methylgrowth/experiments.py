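"""Canned simulation experiments: recovery, null calibration, transfer power.

These drive the synthetic generator through the analysis pipeline and
measure how well the selection and risk-score machinery behaves under known
truth.  They are used by the test suite and the results-reproduction script
but are ordinary library code: each returns a plain dict of measurements.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genes import aggregate, map_probes_to_genes
from .mrs import MrsModel, transfer
from .outcomes import derive_outcomes
from .preprocess import (annotation_filters, background_filter,
                         intensities_to_beta, sample_outlier_screen)
from .selection import InsufficientValidRunsError, consensus_select
from .synthetic import CohortConfig, simulate_cohort


def cohort_gene_table(config: CohortConfig, bmiq: bool = False):
    """Simulate a cohort and push it through QC + gene aggregation.

    Returns (cohort, gene_table, outcome_table).  BMIQ is off by default
    here: these experiments target the selection machinery, and the
    normalization step is rank-preserving within design type (its own
    properties are tested separately).
    """
    from .preprocess import preprocess_pipeline

    cohort = simulate_cohort(config)
    betas = preprocess_pipeline(cohort.intensities, cohort.probe_annotation,
                                bmiq=bmiq, seed=config.seed)
    models = map_probes_to_genes(betas.annotation, cohort.gene_intervals)
    table = aggregate(betas.beta, models)
    outcome_table = derive_outcomes(cohort.phenotypes)
    return cohort, table, outcome_table


def recovery_experiment(n_seeds: int = 10, n_samples: int = 200,
                        n_genes: int = 500, effect: float = 0.5,
                        n_causal: int = 5, outcome: str = "cwg_z",
                        base_seed: int = 0, **consensus_kwargs) -> dict:
    """Planted-signal recovery: does consensus selection find the causal genes?

    For each seed, a cohort with ``n_causal`` planted gene effects of
    magnitude ``effect`` (alternating sign) is generated and analysed
    end-to-end; sensitivity and false positives are measured against the
    generator truth.
    """
    effects = tuple(effect * (-1) ** i for i in range(n_causal))
    per_seed = []
    for s in range(n_seeds):
        config = CohortConfig(n_samples=n_samples, n_genes=n_genes,
                              n_causal_genes=n_causal, effect_sizes=effects,
                              seed=base_seed + 1000 + s)
        cohort, table, outcomes_tab = cohort_gene_table(config)
        X = table.values.T
        y = outcomes_tab.loc[X.index, outcome]
        causal = set(cohort.truth["causal_genes"])
        try:
            cons = consensus_select(X, y, base_seed=config.seed,
                                    **consensus_kwargs)
            found = set(cons.consensus)
            status = "ok"
        except InsufficientValidRunsError:
            found = set()
            status = "no_consensus"
        per_seed.append({
            "seed": config.seed, "status": status,
            "sensitivity": len(found & causal) / len(causal),
            "false_positives": len(found - causal),
            "consensus_size": len(found),
        })
    return {
        "per_seed": per_seed,
        "mean_sensitivity": float(np.mean([r["sensitivity"] for r in per_seed])),
        "mean_false_positives": float(np.mean([r["false_positives"]
                                               for r in per_seed])),
        "max_false_positives": int(max(r["false_positives"] for r in per_seed)),
        "n_seeds": n_seeds,
    }


def null_consensus_experiment(n_seeds: int = 7, n_samples: int = 60,
                              n_genes: int = 100, base_seed: int = 0,
                              max_attempts: int = 20) -> dict:
    """With no planted effects, consensus should usually fail or come back empty."""
    null_like = 0
    per_seed = []
    for s in range(n_seeds):
        config = CohortConfig(n_samples=n_samples, n_genes=n_genes,
                              n_causal_genes=0, effect_sizes=(),
                              seed=base_seed + 2000 + s)
        _, table, outcomes_tab = cohort_gene_table(config)
        X = table.values.T
        y = outcomes_tab.loc[X.index, "cwg_z"]
        try:
            cons = consensus_select(X, y, base_seed=config.seed,
                                    max_attempts=max_attempts)
            outcome = "empty" if not cons.consensus else "consensus"
        except InsufficientValidRunsError:
            outcome = "insufficient_valid"
        null_like += outcome in ("empty", "insufficient_valid")
        per_seed.append({"seed": config.seed, "outcome": outcome})
    return {"per_seed": per_seed, "n_null_like": null_like, "n_seeds": n_seeds,
            "fraction_null_like": null_like / n_seeds}


def _small_gene_table(n_genes: int, n_samples: int, rng: np.random.Generator
                      ) -> pd.DataFrame:
    """Directly sampled gene-level Beta table (genes x samples)."""
    means = rng.beta(2.0, 2.0, size=n_genes)
    logit = np.log(means / (1 - means))[:, None] + rng.normal(
        0.0, 0.5, size=(n_genes, n_samples))
    vals = 1 / (1 + np.exp(-logit))
    return pd.DataFrame(vals,
                        index=[f"G{i:05d}" for i in range(n_genes)],
                        columns=[f"S{j:03d}" for j in range(n_samples)])


def transfer_null_pvalues(model: MrsModel, n_seeds: int = 200,
                          n_external: int = 40, base_seed: int = 0
                          ) -> np.ndarray:
    """Slope p-values of frozen-weight MRS transfer onto null cohorts.

    The external cohorts have methylation with the model's genes present but
    an outcome simulated independently of methylation, emulating a failed
    cross-cohort transfer; under this null the p-values should be uniform.
    """
    pvals = np.empty(n_seeds)
    for s in range(n_seeds):
        rng = np.random.default_rng(base_seed + 3000 + s)
        table = _small_gene_table(len(model.genes), n_external, rng)
        table.index = pd.Index(model.genes)
        y = pd.Series(rng.normal(size=n_external), index=table.columns)
        res = transfer(model, table, y)
        pvals[s] = res["association"].p_value
    return pvals


def transfer_power_experiment(n_seeds: int = 20, n_external: int = 300,
                              effect: float = 0.5, n_causal: int = 5,
                              base_seed: int = 0) -> dict:
    """Transfer onto external cohorts simulated with the SAME causal structure.

    Builds the MRS on a source cohort, then applies frozen weights to fresh
    cohorts sharing the causal genes (same annotation seed, new noise), and
    measures how often the transferred score associates with the outcome.
    """
    from .selection import post_selection_ols
    from .mrs import build_mrs

    effects = tuple(effect * (-1) ** i for i in range(n_causal))
    src_cfg = CohortConfig(n_samples=200, n_genes=100, n_causal_genes=n_causal,
                           effect_sizes=effects, seed=base_seed + 4000)
    src_cohort, src_table, src_out = cohort_gene_table(src_cfg)
    X = src_table.values.T
    y = src_out.loc[X.index, "cwg_z"]
    cons = consensus_select(X, y, base_seed=src_cfg.seed)
    post = post_selection_ols(X, y, cons.consensus)
    model = build_mrs(post, outcome="cwg", tissue=src_cfg.tissue)

    n_sig = 0
    pvals = []
    for s in range(n_seeds):
        # fresh cohort, same causal structure: the source truth genes are
        # pinned as the external cohort's causal genes
        ext_cfg = CohortConfig(n_samples=n_external, n_genes=100,
                               n_causal_genes=n_causal, effect_sizes=effects,
                               causal_genes=tuple(src_cohort.truth["causal_genes"]),
                               seed=base_seed + 5000 + s)
        _, ext_table, ext_out = cohort_gene_table(ext_cfg)
        overlap = [g for g in model.genes if g in ext_table.values.index]
        if not overlap:
            pvals.append(1.0)
            continue
        res = transfer(model, ext_table.values, ext_out["cwg_z"],
                       allow_subset=True)
        pvals.append(res["association"].p_value)
        n_sig += res["association"].p_value < 0.05
    return {"p_values": pvals, "n_significant": n_sig, "n_seeds": n_seeds,
            "fraction_significant": n_sig / n_seeds, "model_genes": model.genes}
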
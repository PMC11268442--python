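"""End-to-end orchestration: preprocess -> outcomes -> aggregate -> select -> MRS.

One run analyses every tissue x weight-outcome combination (two tissues and
three outcomes give the six selection regressions) and writes a JSON
manifest recording the configuration hash, seeds, and a checksum for every
artifact produced.  A selection regression that cannot collect ten
check-mark LASSO fits is recorded as ``no_consensus`` rather than aborting
the run — small-cohort outcomes genuinely may carry no recoverable signal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .genes import aggregate, map_probes_to_genes
from .mrs import associate, build_mrs, compute_mrs, transfer
from .outcomes import derive_outcomes
from .preprocess import preprocess_pipeline
from .selection import (InsufficientValidRunsError, consensus_select,
                        post_selection_ols, screen_covariates)
from .synthetic import CohortConfig, simulate_cohort, simulate_methylation, write_cohort

logger = logging.getLogger(__name__)

OUTCOME_COLUMNS = {"cwg": "cwg_z", "bmi": "bmi_6m_sexstd", "wfl": "wfl_6m_sexstd"}
SCREEN_COLUMNS = {"cwg": "cwg_z", "bmi": "bmi_6m", "wfl": "wfl_6m"}

COVARIATE_COLUMNS = [
    "sex", "mother_bmi", "father_bmi", "gestational_weeks", "maternal_age",
    "vaginal_delivery", "gestational_diabetes", "smoking", "maternal_illness",
    "maternal_medications", "breastmilk_4wk", "breastmilk_16wk",
    "breastmilk_28wk",
]


@dataclass
class TissueInputs:
    methylated: str
    unmethylated: str
    annotation: str


@dataclass
class RunConfig:
    tissues: dict[str, TissueInputs]
    genes_bed: str
    phenotypes: str
    out_dir: str
    outcomes: list[str] = field(default_factory=lambda: ["cwg", "bmi", "wfl"])
    background_threshold: float = 50.0
    min_median_log_intensity: float = 10.0
    bmiq: bool = True
    k_folds: int = 10
    q: int = 6
    n_target_valid: int = 10
    max_attempts: int = 30
    lambda_min_ratio: float = 1e-3
    n_lambdas: int = 100
    seed: int = 0
    transfer_gene_table: str | None = None
    transfer_phenotypes: str | None = None

    def __post_init__(self):
        for name, t in list(self.tissues.items()):
            if isinstance(t, dict):
                self.tissues[name] = TissueInputs(**t)
        bad = [o for o in self.outcomes if o not in OUTCOME_COLUMNS]
        if bad:
            raise ValueError(f"unknown outcomes {bad}; choose from "
                             f"{sorted(OUTCOME_COLUMNS)}")

    def validate_paths(self) -> None:
        paths = [self.genes_bed, self.phenotypes]
        for t in self.tissues.values():
            paths += [t.methylated, t.unmethylated, t.annotation]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save_df(df: pd.DataFrame, name: str, **kw) -> Path:
        path = out / name
        if name.endswith(".csv"):
            df.to_csv(path, **kw)
        else:
            mio.write_matrix(df, path)
        artifacts[name] = _sha256(path)
        return path

    def save_json(obj, name: str) -> Path:
        path = out / name
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, default=str)
        artifacts[name] = _sha256(path)
        return path

    # --- outcomes ---------------------------------------------------------
    pheno = mio.read_phenotypes(config.phenotypes)
    outcome_table = derive_outcomes(pheno)
    save_df(outcome_table, "outcomes.csv")

    # --- covariate screening (per outcome, on the raw outcome scale) ------
    cov_cols = [c for c in COVARIATE_COLUMNS if c in pheno.columns]
    covariates = pheno[cov_cols]
    screen_report = {}
    for oc in config.outcomes:
        res = screen_covariates(covariates, outcome_table[SCREEN_COLUMNS[oc]],
                                seed=config.seed)
        screen_report[oc] = {"selected": res["selected"],
                             "dropped_near_constant": res["dropped_near_constant"]}
    save_json(screen_report, "covariate_screen.json")

    # --- per tissue: preprocess + aggregate -------------------------------
    bed = mio.read_bed(config.genes_bed)
    gene_tables = {}
    qc_report = {}
    for tissue, inputs in config.tissues.items():
        intens = mio.read_intensities(inputs.methylated, inputs.unmethylated)
        ann = mio.read_annotation(inputs.annotation)
        betas = preprocess_pipeline(
            intens, ann,
            background_threshold=config.background_threshold,
            min_median_log_intensity=config.min_median_log_intensity,
            bmiq=config.bmiq, seed=config.seed)
        save_df(betas.beta, f"betas_{tissue}.tsv.gz")
        models = map_probes_to_genes(betas.annotation, bed)
        table = aggregate(betas.beta, models,
                          provenance={"tissue": tissue,
                                      "annotation": inputs.annotation})
        gene_tables[tissue] = table
        save_df(table.values, f"genes_{tissue}.tsv.gz")
        qc_report[tissue] = {"qc_log": betas.qc_log,
                             "n_genes": int(len(table.values)),
                             "dropped_genes": len(table.dropped_genes)}
    save_json(qc_report, "qc_report.json")

    # --- six selection regressions + MRS -----------------------------------
    selection_runs = []
    for tissue, table in gene_tables.items():
        X_all = table.values.T  # samples x genes
        common = X_all.index.intersection(outcome_table.index)
        X = X_all.loc[common]
        for oc in config.outcomes:
            y = outcome_table.loc[common, OUTCOME_COLUMNS[oc]]
            run: dict = {"tissue": tissue, "outcome": oc}
            try:
                cons = consensus_select(
                    X, y, k_folds=config.k_folds, q=config.q,
                    n_target_valid=config.n_target_valid,
                    max_attempts=config.max_attempts,
                    base_seed=config.seed,
                    n_lambdas=config.n_lambdas,
                    lambda_min_ratio=config.lambda_min_ratio)
            except InsufficientValidRunsError as exc:
                run.update(status="no_consensus", n_valid_runs=exc.n_valid)
                selection_runs.append(run)
                logger.info("selection %s/%s: %s", tissue, oc, exc)
                continue
            run.update(status="ok", **{k: v for k, v in cons.report().items()
                                       if k != "per_run"})
            run["per_run"] = cons.report()["per_run"]
            if cons.consensus and len(cons.consensus) < len(common) - 1:
                post = post_selection_ols(X, y, cons.consensus)
                run["post_ols"] = {
                    "coefficients": post.coefficients.to_dict(),
                    "p_values": post.p_values.to_dict(),
                    "adj_r2": post.adj_r2,
                    "marginal": post.marginal.reset_index().to_dict("records"),
                }
                model = build_mrs(post, outcome=oc, tissue=tissue,
                                  metadata={"seed": config.seed,
                                            "config_hash": config.config_hash()})
                model.to_json(out / f"mrs_{tissue}_{oc}.json")
                artifacts[f"mrs_{tissue}_{oc}.json"] = _sha256(
                    out / f"mrs_{tissue}_{oc}.json")
                scores = compute_mrs(table.values[common], model)
                assoc = associate(scores, y, df_model=len(model.genes))
                run["mrs"] = {"adj_r2": assoc.adj_r2, "r2": assoc.r2,
                              "slope": assoc.slope, "p_value": assoc.p_value}
                scores.to_frame().to_csv(out / f"mrs_scores_{tissue}_{oc}.csv")
                artifacts[f"mrs_scores_{tissue}_{oc}.csv"] = _sha256(
                    out / f"mrs_scores_{tissue}_{oc}.csv")
                if config.transfer_gene_table and config.transfer_phenotypes:
                    ext_table = mio.read_matrix(config.transfer_gene_table)
                    ext_pheno = mio.read_phenotypes(config.transfer_phenotypes)
                    ext_out = derive_outcomes(ext_pheno)
                    tr = transfer(model, ext_table,
                                  ext_out[OUTCOME_COLUMNS[oc]],
                                  allow_subset=True)
                    run["transfer"] = {
                        "adj_r2": tr["association"].adj_r2,
                        "slope_p": tr["association"].p_value,
                        "gene_overlap": tr["gene_overlap"],
                    }
            selection_runs.append(run)
    save_json(selection_runs, "selection_runs.json")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_selection_runs": len(selection_runs),
        "selection_status": {f"{r['tissue']}/{r['outcome']}": r["status"]
                             for r in selection_runs},
        "artifacts": artifacts,
    }
    save_json(manifest, "manifest.json")
    return manifest


def make_demo(seed: int = 1, out_dir: str | Path = "demo_run",
              n_genes: int = 150, n_samples: int = 48) -> dict:
    """Generate a two-tissue synthetic workspace, run the pipeline, and
    compare the consensus against the generator truth.

    The cord-blood cohort carries the planted gene effects; the placenta
    cohort shares the same children (phenotypes) but has no planted signal,
    so its regressions are expected to end in ``no_consensus``.
    """
    out = Path(out_dir)
    data = out / "data"
    cord_cfg = CohortConfig(n_samples=n_samples, n_genes=n_genes,
                            tissue="cord_blood", seed=seed)
    cord = simulate_cohort(cord_cfg)
    write_cohort(cord, data / "cord_blood")

    plac_cfg = CohortConfig(n_samples=n_samples, n_genes=n_genes,
                            tissue="placenta", n_causal_genes=0,
                            effect_sizes=(), seed=seed + 1)
    plac = simulate_methylation(plac_cfg)
    plac.phenotypes = cord.phenotypes  # same children, second tissue
    write_cohort(plac, data / "placenta")

    config = RunConfig(
        tissues={
            t: TissueInputs(
                methylated=str(data / t / "intensities_meth.tsv.gz"),
                unmethylated=str(data / t / "intensities_unmeth.tsv.gz"),
                annotation=str(data / t / "probe_annotation.tsv"))
            for t in ("cord_blood", "placenta")
        },
        genes_bed=str(data / "cord_blood" / "genes.bed"),
        phenotypes=str(data / "cord_blood" / "phenotypes.csv"),
        out_dir=str(out / "results"),
        seed=seed,
    )
    manifest = run_all(config)

    # recovery report: consensus vs generator truth (cord blood)
    with open(out / "results" / "selection_runs.json") as fh:
        runs = json.load(fh)
    causal = set(cord.truth["causal_genes"])
    recovery = {}
    for r in runs:
        if r["tissue"] != "cord_blood" or r["status"] != "ok":
            continue
        found = set(r.get("consensus", []))
        recovery[r["outcome"]] = {
            "causal": sorted(causal), "consensus": sorted(found),
            "sensitivity": len(found & causal) / max(len(causal), 1),
            "false_positives": len(found - causal),
        }
    with open(out / "results" / "recovery_report.json", "w") as fh:
        json.dump(recovery, fh, indent=1)
    manifest["recovery"] = recovery
    return manifest
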
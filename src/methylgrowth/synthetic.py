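"""Synthetic methylation-cohort generator.

Emulates a small birth cohort with paired methylation arrays and infant
anthropometrics: per-probe Beta values drawn from a three-state beta
mixture (hypo-/hemi-/hyper-methylated), tissue-specific mixture weights
(cord blood strongly bimodal; placenta with inflated intermediate mass),
an Infinium II dynamic-range compression for the normalization step to
undo, back-computed M/U intensities that reproduce the Beta values exactly
under ``beta = M / (M + U + 100)``, and a phenotype table whose latent
six-month weight outcome carries planted gene-level methylation effects.

The generator writes only plain-text formats (TSV/BED/CSV/JSON); the truth
(causal genes and effects) is kept in a separate file so that pipeline runs
stay blind to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import IntensityMatrix

# tissue-specific three-state mixture: (weights), shared component shapes.
# Cord blood: strong hypomethylated peak (beta < 0.2), smaller peak beta > 0.7.
# Placenta: partially methylated -> more mass between 0.2 and 0.7.
_MIXTURE_SHAPES = ((1.5, 18.0), (5.0, 5.0), (12.0, 3.0))
_TISSUE_WEIGHTS = {
    "cord_blood": (0.60, 0.10, 0.30),
    "placenta": (0.42, 0.33, 0.25),
}

# kg, male minus female at six months (WHO growth-standard medians:
# boys ~7.9 kg, girls ~7.3 kg)
_SEX_EFFECT_WEIGHT_6M = 0.6


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic cohort.

    ``cpgs_per_gene_law`` is a discrete, right-skewed law with support >= 1;
    the default (rounded lognormal, median 7) reproduces a CpG-per-gene
    distribution with mean ~15 and median ~7.  ``effect_sizes`` are signed
    standardized regression coefficients of the latent six-month outcome on
    the (z-scored) causal-gene mean Betas.
    """

    n_samples: int = 48
    n_genes: int = 500
    cpgs_per_gene_law: dict = field(
        default_factory=lambda: {"kind": "lognormal", "median": 7.0, "sigma": 1.23})
    tissue: str = "cord_blood"
    n_causal_genes: int = 5
    effect_sizes: tuple = (0.5, -0.5, 0.5, -0.5, 0.5)
    noise_sd: float = 0.5
    frac_infII: float = 0.84
    seed: int = 0
    # realism knobs
    frac_failed_probes: float = 0.01
    frac_snp_probes: float = 0.02
    frac_sex_chrom_genes: float = 0.04
    frac_orphan_probes: float = 0.02
    infii_compression: float = 0.7
    sex_female_prob: float = 0.56
    causal_cpg_fraction: float = 1.0
    # pin the causal genes by id (e.g. to give an external validation cohort
    # the same causal structure as a source cohort); None -> drawn at random
    causal_genes: tuple | None = None

    def __post_init__(self):
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("counts must be positive")
        if self.n_causal_genes > self.n_genes:
            raise ValueError("n_causal_genes exceeds n_genes")
        if len(self.effect_sizes) != self.n_causal_genes:
            raise ValueError("effect_sizes length must equal n_causal_genes")
        if not 0 <= self.frac_infII <= 1:
            raise ValueError("frac_infII must be in [0, 1]")
        if self.tissue not in _TISSUE_WEIGHTS:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if not 0 < self.causal_cpg_fraction <= 1:
            raise ValueError("causal_cpg_fraction must be in (0, 1]")


@dataclass
class SyntheticCohort:
    intensities: IntensityMatrix
    probe_annotation: pd.DataFrame  # probe_id index: chrom,pos,design_type,snp_flag,sex_chrom_flag
    gene_intervals: pd.DataFrame    # chrom,start,end,gene_id (BED convention)
    betas: pd.DataFrame             # observed (post-compression) latent Betas
    phenotypes: pd.DataFrame | None
    truth: dict
    config: CohortConfig


def _draw_cpg_counts(law: dict, n_genes: int, rng: np.random.Generator) -> np.ndarray:
    kind = law.get("kind", "lognormal")
    if kind == "point":
        return np.full(n_genes, int(law["value"]))
    if kind == "lognormal":
        med = float(law.get("median", 7.0))
        sigma = float(law.get("sigma", 1.23))
        draws = rng.lognormal(mean=np.log(med), sigma=sigma, size=n_genes)
        return np.maximum(1, np.rint(draws).astype(int))
    raise ValueError(f"unknown cpgs_per_gene_law kind {kind!r}")


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_methylation(config: CohortConfig) -> SyntheticCohort:
    """Generate probe annotation, gene intervals, Betas and intensities.

    Deterministic given ``config`` (including its seed).  Phenotypes are
    attached by :func:`simulate_anthropometrics`.
    """
    rng = np.random.default_rng(config.seed)
    n_genes, n_samples = config.n_genes, config.n_samples

    cpg_counts = _draw_cpg_counts(config.cpgs_per_gene_law, n_genes, rng)
    n_sex_genes = int(round(config.frac_sex_chrom_genes * n_genes))

    # genome layout: disjoint genes tiled over chr1..chr22, trailing genes on chrX
    gene_ids = [f"G{idx:05d}" for idx in range(n_genes)]
    chroms, starts, ends = [], [], []
    autosomes = [f"chr{c}" for c in range(1, 23)]
    pos_cursor = {c: 10_000 for c in autosomes + ["chrX"]}
    for idx in range(n_genes):
        chrom = "chrX" if idx >= n_genes - n_sex_genes else autosomes[idx % 22]
        start = pos_cursor[chrom]
        length = int(cpg_counts[idx]) * 100 + 200
        chroms.append(chrom)
        starts.append(start)
        ends.append(start + length)
        pos_cursor[chrom] = start + length + 1_000
    gene_intervals = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, "gene_id": gene_ids})

    # probes inside genes at fixed spacing; 1-based positions
    probe_rows = []
    for idx in range(n_genes):
        for j in range(cpg_counts[idx]):
            pos0 = starts[idx] + 100 + 100 * j  # 0-based, inside [start, end)
            probe_rows.append((chroms[idx], pos0 + 1, idx))
    # orphan (intergenic) probes
    n_orphans = int(round(config.frac_orphan_probes * len(probe_rows)))
    for j in range(n_orphans):
        chrom = autosomes[j % 22]
        probe_rows.append((chrom, pos_cursor[chrom] + 500 + 100 * j, -1))

    n_probes = len(probe_rows)
    probe_ids = [f"cg{idx:07d}" for idx in range(n_probes)]
    ann = pd.DataFrame(probe_rows, columns=["chrom", "pos", "gene_idx"])
    ann.index = pd.Index(probe_ids, name="probe_id")
    ann["design_type"] = np.where(rng.random(n_probes) < config.frac_infII, "II", "I")
    ann["snp_flag"] = rng.random(n_probes) < config.frac_snp_probes
    ann["sex_chrom_flag"] = (ann["chrom"] == "chrX").values

    # latent true Betas: per-probe mixture mean + gene-sample and probe-sample noise
    w = np.asarray(_TISSUE_WEIGHTS[config.tissue])
    comp = rng.choice(3, size=n_probes, p=w)
    shapes = np.asarray(_MIXTURE_SHAPES)
    probe_mean = rng.beta(shapes[comp, 0], shapes[comp, 1])
    probe_mean = np.clip(probe_mean, 1e-4, 1 - 1e-4)

    gene_effect = rng.normal(0.0, 0.35, size=(n_genes + 1, n_samples))
    probe_noise = rng.normal(0.0, 0.25, size=(n_probes, n_samples))
    logit_true = (_logit(probe_mean)[:, None]
                  + gene_effect[ann["gene_idx"].values, :]
                  + probe_noise)
    beta_true = _expit(logit_true)

    # Infinium II dynamic-range compression toward 0.5 on the logit scale
    is_ii = (ann["design_type"] == "II").values
    beta_obs = beta_true.copy()
    beta_obs[is_ii] = _expit(config.infii_compression * logit_true[is_ii])
    beta_obs = np.clip(beta_obs, 1e-6, 1 - 1e-6)

    # failed probes: both channels at noise level in every sample
    failed = rng.random(n_probes) < config.frac_failed_probes

    # exact Beta -> intensity inversion: with S = M + U,
    # M = beta * (S + 100) and U = S - M give M / (M + U + 100) = beta.
    signal = rng.lognormal(mean=np.log(3000.0), sigma=0.35,
                           size=(n_probes, n_samples))
    floor = 100.0 * beta_obs / (1.0 - beta_obs) + 50.0
    signal = np.maximum(np.maximum(signal, 200.0), floor)
    meth = beta_obs * (signal + 100.0)
    unmeth = signal - meth
    noise_lo = rng.uniform(1.0, 40.0, size=(int(failed.sum()), n_samples, 2))
    meth[failed] = noise_lo[:, :, 0]
    unmeth[failed] = noise_lo[:, :, 1]

    samples = [f"S{idx:03d}" for idx in range(n_samples)]
    intensities = IntensityMatrix(
        pd.DataFrame(meth, index=probe_ids, columns=samples),
        pd.DataFrame(unmeth, index=probe_ids, columns=samples))
    betas = pd.DataFrame(beta_obs, index=probe_ids, columns=samples)

    # causal genes: autosomal, not entirely failed/SNP-flagged
    clean = (~ann["snp_flag"].values) & (~failed)
    if config.causal_genes is not None:
        if len(config.causal_genes) != config.n_causal_genes:
            raise ValueError("causal_genes length must equal n_causal_genes")
        idx_of = {g: i for i, g in enumerate(gene_ids)}
        missing = [g for g in config.causal_genes if g not in idx_of]
        if missing:
            raise ValueError(f"pinned causal genes not in cohort: {missing}")
        causal_idx = np.array([idx_of[g] for g in config.causal_genes], dtype=int)
        if (causal_idx >= n_genes - n_sex_genes).any():
            raise ValueError("pinned causal genes fall on a sex chromosome")
    else:
        usable = []
        for idx in range(n_genes - n_sex_genes):
            members = np.flatnonzero((ann["gene_idx"].values == idx) & clean)
            if members.size >= 1:
                usable.append(idx)
        causal_idx = rng.choice(np.asarray(usable), size=config.n_causal_genes,
                                replace=False) if config.n_causal_genes else \
            np.array([], dtype=int)
    truth = {
        "causal_genes": [gene_ids[i] for i in causal_idx],
        "effect_sizes": list(map(float, config.effect_sizes)),
        "tissue": config.tissue,
        "seed": config.seed,
    }

    ann_out = ann[["chrom", "pos", "design_type", "snp_flag", "sex_chrom_flag"]]
    return SyntheticCohort(intensities=intensities, probe_annotation=ann_out,
                           gene_intervals=gene_intervals, betas=betas,
                           phenotypes=None, truth=truth, config=config,
                           )


def _causal_gene_values(cohort: SyntheticCohort, rng: np.random.Generator
                        ) -> np.ndarray:
    """Mean observed Beta of each causal gene over its QC-clean probes.

    Mirrors what the analysis pipeline will compute: SNP-flagged and failed
    (background-level) probes are excluded from the mean.  When
    ``causal_cpg_fraction`` < 1 the effect is carried by a random subset of
    the gene's CpGs (to emulate site-driven associations); the chosen sites
    are recorded in the truth.
    """
    cfg = cohort.config
    ann = cohort.probe_annotation
    total = cohort.intensities.total()
    failed = (total.values < 100.0).all(axis=1)
    clean = (~ann["snp_flag"].values) & (~failed)
    genes = cohort.gene_intervals.set_index("gene_id")
    vals = np.zeros((len(cohort.truth["causal_genes"]), cfg.n_samples))
    causal_sites: dict[str, list[str]] = {}
    for i, gid in enumerate(cohort.truth["causal_genes"]):
        g = genes.loc[gid]
        in_gene = ((ann["chrom"] == g["chrom"]).values
                   & (ann["pos"].values - 1 >= g["start"])
                   & (ann["pos"].values - 1 < g["end"]) & clean)
        members = np.flatnonzero(in_gene)
        if members.size == 0:  # every member probe failed/flagged: use all
            members = np.flatnonzero(
                (ann["chrom"] == g["chrom"]).values
                & (ann["pos"].values - 1 >= g["start"])
                & (ann["pos"].values - 1 < g["end"]))
        if cfg.causal_cpg_fraction < 1.0 and members.size > 1:
            k = max(1, int(round(cfg.causal_cpg_fraction * members.size)))
            members = rng.choice(members, size=k, replace=False)
        causal_sites[gid] = list(ann.index[members])
        vals[i] = cohort.betas.values[members].mean(axis=0)
    cohort.truth["causal_sites"] = causal_sites
    return vals


def simulate_anthropometrics(cohort: SyntheticCohort,
                             config: CohortConfig | None = None) -> pd.DataFrame:
    """Attach a phenotype table whose latent outcome carries the gene effects.

    The latent six-month outcome is ``sum_g effect_g * z(geneBeta_g) +
    noise``; it is injected into the six-month weight-for-age z-score, so
    conditional weight gain, BMI and weight-for-length all correlate with
    it.  A fixed male-female weight difference at six months plants the sex
    association the covariate screen is expected to find.  All other
    covariates are drawn independently of methylation.
    """
    config = config or cohort.config
    if config.n_samples != len(cohort.intensities.samples):
        raise ValueError("config.n_samples does not match cohort")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n = config.n_samples

    gene_vals = _causal_gene_values(cohort, rng)
    gsd = gene_vals.std(axis=1, ddof=1)
    gsd[gsd == 0] = 1.0
    z = (gene_vals - gene_vals.mean(axis=1, keepdims=True)) / gsd[:, None]
    effects = np.asarray(config.effect_sizes, dtype=float)
    latent = effects @ z + config.noise_sd * rng.normal(size=n)

    female = rng.random(n) < config.sex_female_prob
    male = (~female).astype(float)

    waz_birth = rng.normal(size=n)
    laz_birth = 0.5 * waz_birth + np.sqrt(0.75) * rng.normal(size=n)
    laz_6m = 0.6 * laz_birth + 0.8 * rng.normal(size=n)
    age_6m = 182.0 + rng.normal(0.0, 7.0, size=n)
    lat_sd = latent.std(ddof=1)
    latent_z = (latent - latent.mean()) / (lat_sd if lat_sd > 0 else 1.0)
    waz_6m = (0.5 * waz_birth + 0.15 * laz_birth + 0.1 * laz_6m
              + 0.0005 * (age_6m - 182.0) + 0.9 * latent_z
              + 0.15 * rng.normal(size=n))

    weight_birth = 3.35 + 0.45 * waz_birth + 0.12 * male
    length_birth = 49.9 + 1.9 * laz_birth
    weight_6m = 7.7 + 0.75 * waz_6m + _SEX_EFFECT_WEIGHT_6M * male
    length_6m = 66.0 + 2.0 * laz_6m

    pheno = pd.DataFrame({
        "child_id": list(cohort.intensities.samples),
        "sex": np.where(female, "female", "male"),
        "weight_birth": weight_birth,
        "length_birth": length_birth,
        "weight_6m": weight_6m,
        "length_6m": length_6m,
        "age_6m_days": age_6m,
        "waz_birth": waz_birth,
        "waz_6m": waz_6m,
        "laz_birth": laz_birth,
        "laz_6m": laz_6m,
        # covariates, independent of methylation
        "mother_bmi": rng.normal(24.5, 4.5, size=n),
        "father_bmi": rng.normal(28.6, 4.5, size=n),
        "gestational_weeks": rng.normal(38.9, 1.1, size=n),
        "maternal_age": rng.normal(31.8, 4.3, size=n),
        "vaginal_delivery": (rng.random(n) < 0.708).astype(int),
        "gestational_diabetes": (rng.random(n) < 0.0625).astype(int),
        "smoking": (rng.random(n) < 1.0 / 48.0).astype(int),
        "maternal_illness": (rng.random(n) < 1.0 / 48.0).astype(int),
        "maternal_medications": (rng.random(n) < 0.688).astype(int),
        "breastmilk_4wk": (rng.random(n) < 0.667).astype(int),
        "breastmilk_16wk": (rng.random(n) < 0.521).astype(int),
        "breastmilk_28wk": (rng.random(n) < 0.396).astype(int),
    }).set_index("child_id")
    cohort.phenotypes = pheno
    cohort.truth["latent_outcome"] = [float(v) for v in latent]
    return pheno


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Convenience: methylation plus anthropometrics in one call."""
    cohort = simulate_methylation(config)
    simulate_anthropometrics(cohort, config)
    return cohort


# ---------------------------------------------------------------------------
# writers


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict:
    """Write the cohort as plain-text files; truth goes to a separate file.

    Returns a manifest dict (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "methylated": out / "intensities_meth.tsv.gz",
        "unmethylated": out / "intensities_unmeth.tsv.gz",
        "annotation": out / "probe_annotation.tsv",
        "genes_bed": out / "genes.bed",
        "phenotypes": out / "phenotypes.csv",
        "truth": out / "truth.json",
    }
    from .io import write_matrix

    write_matrix(cohort.intensities.methylated, paths["methylated"],
                 float_format="%.4f")
    write_matrix(cohort.intensities.unmethylated, paths["unmethylated"],
                 float_format="%.4f")
    ann = cohort.probe_annotation.copy()
    ann["snp_flag"] = ann["snp_flag"].astype(int)
    ann["sex_chrom_flag"] = ann["sex_chrom_flag"].astype(int)
    ann.to_csv(paths["annotation"], sep="\t")
    cohort.gene_intervals.to_csv(paths["genes_bed"], sep="\t", header=False,
                                 index=False)
    if cohort.phenotypes is not None:
        cohort.phenotypes.to_csv(paths["phenotypes"])
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    manifest = {
        "config": asdict(cohort.config),
        "seed": cohort.config.seed,
        "files": {k: str(v.name) for k, v in paths.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
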
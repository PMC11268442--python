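"""Probe-to-gene interval mapping and gene-level Beta aggregation.

Gene methylation is summarized as the unweighted mean Beta across the CpG
probes falling inside the gene's genomic interval.  Intervals follow the
BED convention (0-based, half-open); probe positions are 1-based and are
converted internally.  A probe overlapping several genes contributes to all
of them; probes inside no gene are logged and dropped from gene analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    probes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")


@dataclass
class GeneMethylationTable:
    """Gene x sample mean-Beta matrix with CpG membership bookkeeping."""

    values: pd.DataFrame                 # genes x samples
    cpg_counts: pd.Series                # per gene
    membership: dict[str, list[str]]     # gene -> probe ids
    dropped_genes: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _norm_chrom(c: str) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def map_probes_to_genes(probe_annotation: pd.DataFrame,
                        gene_intervals: pd.DataFrame) -> list[GeneModel]:
    """Assign probes to every gene interval containing their position.

    ``probe_annotation`` needs columns chrom, pos (1-based);
    ``gene_intervals`` needs chrom, start, end, gene_id (BED, 0-based
    half-open).  Chromosome names are matched after normalizing an optional
    "chr" prefix.  Orphan probes are logged.
    """
    trees: dict[str, IntervalTree] = {}
    genes: dict[str, GeneModel] = {}
    for row in gene_intervals.itertuples(index=False):
        chrom = _norm_chrom(row.chrom)
        gm = GeneModel(str(row.gene_id), chrom, int(row.start), int(row.end))
        genes[gm.gene_id] = gm
        trees.setdefault(chrom, IntervalTree()).addi(gm.start, gm.end, gm.gene_id)

    probe_chroms = {_norm_chrom(c) for c in probe_annotation["chrom"].unique()}
    if trees and not (probe_chroms & set(trees)):
        raise ValueError(
            "no shared chromosome names between probes and gene intervals "
            f"(probes: {sorted(probe_chroms)[:5]}, genes: {sorted(trees)[:5]})")

    n_orphans = 0
    for probe_id, row in zip(probe_annotation.index,
                             probe_annotation[["chrom", "pos"]].itertuples(index=False)):
        chrom = _norm_chrom(row.chrom)
        pos0 = int(row.pos) - 1  # 1-based -> 0-based
        hits = trees[chrom][pos0] if chrom in trees else ()
        if not hits:
            n_orphans += 1
            continue
        for iv in hits:
            genes[iv.data].probes.append(str(probe_id))
    if n_orphans:
        logger.info("map_probes_to_genes: %d probes outside all gene intervals",
                    n_orphans)
    return list(genes.values())


def aggregate(betas: pd.DataFrame, gene_models: list[GeneModel],
              provenance: dict | None = None) -> GeneMethylationTable:
    """Mean Beta per gene per sample over member probes surviving QC.

    Genes whose member probes were all removed upstream are dropped and
    logged.  ``betas`` is probes x samples.
    """
    present = betas.index
    values = {}
    counts = {}
    membership = {}
    dropped = []
    for gm in gene_models:
        members = [p for p in gm.probes if p in present]
        if not members:
            dropped.append(gm.gene_id)
            continue
        values[gm.gene_id] = betas.loc[members].mean(axis=0)
        counts[gm.gene_id] = len(members)
        membership[gm.gene_id] = members
    if dropped:
        logger.info("aggregate: dropped %d genes with no surviving probes",
                    len(dropped))
    if not values:
        raise ValueError("no genes with surviving probes")
    table = pd.DataFrame(values).T
    table.index.name = "gene_id"
    return GeneMethylationTable(
        values=table,
        cpg_counts=pd.Series(counts, name="n_cpgs"),
        membership=membership,
        dropped_genes=dropped,
        provenance=provenance or {},
    )


def cpg_count_summary(table: GeneMethylationTable) -> dict:
    c = table.cpg_counts
    return {"min": int(c.min()), "max": int(c.max()),
            "mean": float(c.mean()), "median": float(c.median()),
            "n_genes": int(len(c))}
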
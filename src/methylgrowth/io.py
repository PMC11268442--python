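"""Readers and writers for the plain-text interchange formats.

All stage inputs/outputs are inspectable text: probes x samples TSV
(optionally gzipped) for intensities and Betas, TSV probe annotation, BED
gene intervals, CSV phenotype/outcome tables, JSON for models/manifests.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path

import pandas as pd

from .preprocess import IntensityMatrix

ANNOTATION_COLUMNS = ["chrom", "pos", "design_type", "snp_flag", "sex_chrom_flag"]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Probes-as-rows TSV with a header row of sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path, digits: int = 6,
                 float_format: str | None = None) -> None:
    """Write a probes-as-rows TSV; gzip output is byte-reproducible.

    The gzip header timestamp is pinned to zero so identical data yields an
    identical file (run manifests record content checksums).
    """
    fmt = float_format or f"%.{digits}g"
    text = df.to_csv(sep="\t", float_format=fmt)
    data = text.encode()
    if str(path).endswith(".gz"):
        buf = _io.BytesIO()
        with gzip.GzipFile(filename="", mode="wb", fileobj=buf, mtime=0) as gz:
            gz.write(data)
        data = buf.getvalue()
    Path(path).write_bytes(data)


def read_intensities(meth_path: str | Path, unmeth_path: str | Path
                     ) -> IntensityMatrix:
    return IntensityMatrix(read_matrix(meth_path), read_matrix(unmeth_path))


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    ann["snp_flag"] = ann["snp_flag"].astype(bool)
    ann["sex_chrom_flag"] = ann["sex_chrom_flag"].astype(bool)
    return ann


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED 3+1: chrom, start, end, gene_id (0-based, half-open)."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2, 3],
                      names=["chrom", "start", "end", "gene_id"])
    if (bed["start"] >= bed["end"]).any():
        bad = bed[bed["start"] >= bed["end"]].iloc[0]
        raise ValueError(f"invalid BED interval for {bad['gene_id']}")
    return bed


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
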
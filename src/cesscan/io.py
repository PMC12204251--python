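"""Tab-delimited readers and writers for the pipeline's tables.

All interchange formats are plain TSV with headers:

* site table: gene_id, chrom, pos, ref, alt, mu, qual, consequence,
  lof_hc, missense_score
* gene table (BED-like): chrom, start, end, gene_id — multiple rows per
  gene for multi-interval CDS; intervals half-open 0-based, site
  positions 1-based
* de novo list: chrom, pos, ref, alt, subcohort
* population allele counts: gene_id, k, mu, n
* per-gene scores: gene_id plus score columns (loeuf, shet_prior, ...)
"""

from __future__ import annotations

from typing import Union

import pandas as pd

from .annotation import GeneModel

PathLike = Union[str, "os.PathLike[str]"]  # noqa: F821

SITE_COLUMNS = [
    "gene_id", "chrom", "pos", "ref", "alt", "mu", "qual",
    "consequence", "lof_hc", "missense_score",
]


def read_sites(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    df["pos"] = df["pos"].astype(int)
    df["mu"] = df["mu"].astype(float)
    df["lof_hc"] = df["lof_hc"].astype(bool)
    return df


def write_sites(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_genes_bed(path: PathLike) -> list[GeneModel]:
    """BED-like gene table -> GeneModel list (rows grouped by gene)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"chrom", "start", "end", "gene_id"}
    if not needed <= set(df.columns):
        raise ValueError(f"gene table must have columns {sorted(needed)}")
    genes = []
    for gid, sub in df.groupby("gene_id", sort=True):
        intervals = list(zip(sub["start"].astype(int),
                             sub["end"].astype(int)))
        genes.append(GeneModel(gene_id=str(gid), cds_intervals=intervals))
    return genes


def write_genes_bed(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_denovo(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"chrom", "pos", "ref", "alt", "subcohort"}
    if not needed <= set(df.columns):
        raise ValueError(f"de novo table must have columns {sorted(needed)}")
    df["pos"] = df["pos"].astype(int)
    return df


def read_allele_counts(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"gene_id", "k", "mu", "n"}
    if not needed <= set(df.columns):
        raise ValueError(
            f"allele-count table must have columns {sorted(needed)}"
        )
    if df["n"].nunique() > 1:
        raise ValueError("mixed sample sizes n in one allele-count table")
    df["k"] = df["k"].astype(int)
    df["mu"] = df["mu"].astype(float)
    return df


def read_gene_scores(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError("gene score table must have a gene_id column")
    return df


def write_tsv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
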
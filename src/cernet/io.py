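"""Readers and writers for the pipeline's tabular formats.

Everything is plain TSV: expression matrices (header = sample ids, first
column = gene ids), two-column interaction edge lists, triplet/score tables
and level maps.  Floats are written with ``%.10g`` so repeated runs with the
same seed produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import (
    COUNT_FILTER_MIN_READS,
    DifferentialStats,
    ExpressionDataset,
    FormatError,
    InteractionSet,
    Triplet,
)

FLOAT_FMT = "%.10g"


def read_expression_matrix(path: str | Path, rna_class: str) -> pd.DataFrame:
    """Read one genes x samples TSV matrix.

    The header row carries sample ids; the first column gene ids.  Duplicate
    gene ids, NA cells, non-numeric cells and empty files are rejected with
    an error naming the offender.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no data rows") from None
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no data rows")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise FormatError(f"{path}: missing value in row {gene!r}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from None
    values.index.name = "gene"
    # validation of sign/class happens in ExpressionDataset; re-check here so
    # a single-matrix read already fails fast
    if (values.to_numpy() < 0).any():
        gene = values.index[(values.to_numpy() < 0).any(axis=1)][0]
        raise FormatError(f"{path}: negative value in row {gene!r}")
    if rna_class not in ("mRNA", "miRNA", "lncRNA"):
        raise ValueError(f"unknown RNA class {rna_class!r}")
    return values


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df = df.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_sample_groups(path: str | Path) -> pd.Series:
    """Read a two-column TSV ``sample<TAB>group``."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns (sample, group)")
    df.columns = ["sample", "group"]
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    return pd.Series(df["group"].values, index=df["sample"].values, name="group")


def write_sample_groups(groups: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", index=False
    )


def read_expression_dataset(
    mrna_path: str | Path,
    mirna_path: str | Path,
    lncrna_path: str | Path,
    groups_path: str | Path,
    value_kind: str = "normalized",
) -> ExpressionDataset:
    return ExpressionDataset(
        read_expression_matrix(mrna_path, "mRNA"),
        read_expression_matrix(mirna_path, "miRNA"),
        read_expression_matrix(lncrna_path, "lncRNA"),
        read_sample_groups(groups_path),
        value_kind=value_kind,
    )


def read_edge_list(path: str | Path) -> set[tuple[str, str]]:
    """Read a headered two-column TSV ``source<TAB>target`` into a pair set."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected exactly two columns")
    if df.isna().any().any():
        raise FormatError(f"{path}: empty id in edge list")
    return set(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_edge_list(pairs: Iterable[tuple[str, str]], path: str | Path,
                    columns: tuple[str, str] = ("source", "target")) -> None:
    rows = sorted(pairs)
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, sep="\t", index=False)


def read_interactions(mirna_mrna_path: str | Path, mirna_lncrna_path: str | Path) -> InteractionSet:
    return InteractionSet(
        mirna_mrna=read_edge_list(mirna_mrna_path),
        mirna_lncrna=read_edge_list(mirna_lncrna_path),
    )


def filter_low_expression(ds: ExpressionDataset,
                          min_reads: dict[str, int] | None = None,
                          prevalence: float = 0.5) -> ExpressionDataset:
    """Prevalence filter on raw counts.

    A gene is retained iff its count reaches the class minimum (mRNA 5,
    miRNA 1, lncRNA 1 by default) in strictly more than ``prevalence`` of the
    samples.  Defined on counts only; a normalized dataset is refused.
    Idempotent, order preserving.
    """
    if ds.value_kind != "counts":
        raise ValueError("the prevalence filter is defined on read counts, "
                         f"got value_kind={ds.value_kind!r}")
    min_reads = dict(COUNT_FILTER_MIN_READS if min_reads is None else min_reads)
    n = len(ds.samples)

    def keep(df: pd.DataFrame, rna_class: str) -> pd.DataFrame:
        frac = (df.to_numpy() >= min_reads[rna_class]).sum(axis=1) / n
        return df.loc[frac > prevalence]

    return ExpressionDataset(
        keep(ds.mrna, "mRNA"), keep(ds.mirna, "miRNA"), keep(ds.lncrna, "lncRNA"),
        ds.sample_groups, value_kind="counts",
    )


# -- triplet and score tables -------------------------------------------

TRIPLET_COLUMNS = ["lncRNA", "miRNA", "mRNA", "shared_mirna_p",
                   "pcc_lm", "pcc_mm", "pcc_ml", "pcc_lm_p", "pcc_mm_p", "pcc_ml_p"]


def triplets_to_frame(triplets: Iterable[Triplet]) -> pd.DataFrame:
    rows = [
        (t.lncrna, t.mirna, t.mrna, t.shared_mirna_p,
         t.pcc_lm, t.pcc_mm, t.pcc_ml, *t.pcc_ps)
        for t in triplets
    ]
    return pd.DataFrame(rows, columns=TRIPLET_COLUMNS)


def frame_to_triplets(df: pd.DataFrame) -> list[Triplet]:
    out = []
    for row in df.itertuples(index=False):
        out.append(Triplet(
            lncrna=row.lncRNA, mirna=row.miRNA, mrna=row.mRNA,
            shared_mirna_p=float(row.shared_mirna_p),
            pcc_lm=float(row.pcc_lm), pcc_mm=float(row.pcc_mm), pcc_ml=float(row.pcc_ml),
            pcc_ps=(float(row.pcc_lm_p), float(row.pcc_mm_p), float(row.pcc_ml_p)),
        ))
    return out


def write_triplets(triplets: Iterable[Triplet], path: str | Path) -> None:
    triplets_to_frame(triplets).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_triplets(path: str | Path) -> list[Triplet]:
    df = pd.read_csv(path, sep="\t", header=0)
    missing = [c for c in TRIPLET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: triplet table lacks columns {missing}")
    return frame_to_triplets(df)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_de_table(path: str | Path, rna_class: str = "mRNA") -> DifferentialStats:
    """Import an externally computed differential-expression table.

    Expects TSV columns ``gene``, ``log2FC``, ``p``; p must lie in (0, 1]
    (p = 0 is rejected because downstream scores take -log10 p).
    """
    df = pd.read_csv(path, sep="\t", header=0)
    for col in ("gene", "log2FC", "p"):
        if col not in df.columns:
            raise FormatError(f"{path}: differential table lacks column {col!r}")
    df = df.set_index("gene")
    p = df["p"].to_numpy(dtype=float)
    bad = (p <= 0) | (p > 1)
    if bad.any():
        raise FormatError(f"{path}: p-value outside (0, 1] for gene {df.index[bad][0]!r}")
    return DifferentialStats(df[["log2FC", "p"]].astype(float), rna_class)
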
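"""Core in-memory containers for the ceRNA triplet pipeline.

Expression is held as one pandas DataFrame per RNA class (genes x samples)
inside an :class:`ExpressionDataset`; curated interaction edges live in an
:class:`InteractionSet`.  Both are validated on construction so that every
downstream stage can assume a sample-matched, duplicate-free universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

RNA_CLASSES = ("mRNA", "miRNA", "lncRNA")

#: read-count prevalence thresholds: a gene is kept iff its count reaches the
#: class minimum in strictly more than half of the samples
COUNT_FILTER_MIN_READS = {"mRNA": 5, "miRNA": 1, "lncRNA": 1}


class FormatError(ValueError):
    """Raised for malformed tabular inputs (names the offending row/column)."""


def _check_matrix(df: pd.DataFrame, rna_class: str) -> pd.DataFrame:
    if rna_class not in RNA_CLASSES:
        raise ValueError(f"unknown RNA class {rna_class!r}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r} in {rna_class} matrix")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise FormatError(f"missing value for gene {gene!r} in {rna_class} matrix")
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        gene = df.index[(values < 0).any(axis=1)][0]
        raise FormatError(f"negative expression for gene {gene!r} in {rna_class} matrix")
    return df.astype(float)


@dataclass
class ExpressionDataset:
    """Sample-matched mRNA / miRNA / lncRNA expression with group labels.

    Parameters
    ----------
    mrna, mirna, lncrna
        genes x samples matrices; the three must share an identical,
        identically ordered sample axis.
    sample_groups
        Mapping sample id -> group name (e.g. ``control``, ``caseA``).
    value_kind
        ``"counts"`` (raw reads; required by the prevalence filter) or
        ``"normalized"`` (TPM/RPM-like; used by all correlation stages).
    """

    mrna: pd.DataFrame
    mirna: pd.DataFrame
    lncrna: pd.DataFrame
    sample_groups: pd.Series
    value_kind: str = "normalized"

    def __post_init__(self) -> None:
        if self.value_kind not in ("counts", "normalized"):
            raise ValueError(f"value_kind must be counts|normalized, got {self.value_kind!r}")
        self.mrna = _check_matrix(self.mrna, "mRNA")
        self.mirna = _check_matrix(self.mirna, "miRNA")
        self.lncrna = _check_matrix(self.lncrna, "lncRNA")
        samples = list(self.mrna.columns)
        for name, df in (("miRNA", self.mirna), ("lncRNA", self.lncrna)):
            if list(df.columns) != samples:
                raise FormatError(
                    f"sample ids of the {name} matrix do not match the mRNA matrix "
                    "(sample-matched design requires identical order)"
                )
        if not isinstance(self.sample_groups, pd.Series):
            self.sample_groups = pd.Series(dict(self.sample_groups))
        missing = [s for s in samples if s not in self.sample_groups.index]
        if missing:
            raise FormatError(f"no group label for sample {missing[0]!r}")
        self.sample_groups = self.sample_groups.loc[samples]

    # -- convenience -----------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.mrna.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.sample_groups:
            seen.setdefault(g, None)
        return list(seen)

    def matrix(self, rna_class: str) -> pd.DataFrame:
        return {"mRNA": self.mrna, "miRNA": self.mirna, "lncRNA": self.lncrna}[rna_class]

    def samples_of(self, group: str) -> list[str]:
        return list(self.sample_groups.index[self.sample_groups == group])

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionDataset":
        samples = list(samples)
        return ExpressionDataset(
            self.mrna[samples], self.mirna[samples], self.lncrna[samples],
            self.sample_groups.loc[samples], self.value_kind,
        )

    def subset_group(self, group: str) -> "ExpressionDataset":
        return self.subset_samples(self.samples_of(group))

    def log2(self, rna_class: str) -> pd.DataFrame:
        """log2(x + 1) of a class matrix — the scale of all correlation work."""
        return np.log2(self.matrix(rna_class) + 1.0)


@dataclass
class InteractionSet:
    """Experimentally supported miRNA-mRNA and miRNA-lncRNA edges."""

    mirna_mrna: set[tuple[str, str]] = field(default_factory=set)
    mirna_lncrna: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for pairs, name in ((self.mirna_mrna, "miRNA-mRNA"), (self.mirna_lncrna, "miRNA-lncRNA")):
            for a, b in pairs:
                if not a or not b:
                    raise FormatError(f"empty id in {name} edge ({a!r}, {b!r})")

    def mirnas(self) -> set[str]:
        return {m for m, _ in self.mirna_mrna} | {m for m, _ in self.mirna_lncrna}

    def targets_of_mirna(self, mirna: str) -> set[str]:
        return {t for m, t in self.mirna_mrna if m == mirna}

    def mirnas_of_mrna(self, mrna: str) -> set[str]:
        return {m for m, t in self.mirna_mrna if t == mrna}

    def mirnas_of_lncrna(self, lncrna: str) -> set[str]:
        return {m for m, t in self.mirna_lncrna if t == lncrna}


@dataclass(frozen=True)
class Triplet:
    """One (lncRNA, miRNA, mRNA) ceRNA candidate with its discovery statistics.

    ``pcc_lm``/``pcc_mm``/``pcc_ml`` are the Pearson correlations of the
    lncRNA-mRNA, miRNA-mRNA and miRNA-lncRNA pairs in control samples;
    ``pcc_ps`` their two-sided p-values; ``shared_mirna_p`` the upper-tail
    hypergeometric p for the shared-miRNA overlap of the lncRNA/mRNA pair.
    """

    lncrna: str
    mirna: str
    mrna: str
    shared_mirna_p: float = np.nan
    pcc_lm: float = np.nan
    pcc_mm: float = np.nan
    pcc_ml: float = np.nan
    pcc_ps: tuple[float, float, float] = (np.nan, np.nan, np.nan)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.lncrna, self.mirna, self.mrna)

    @property
    def genes(self) -> tuple[str, str, str]:
        return (self.lncrna, self.mirna, self.mrna)


@dataclass
class TripletScore:
    """Composite dysregulated score S of one triplet in a case condition.

    S = sum of three node (dot) scores, three edge scores and the influence
    score; the identity is asserted on construction.
    """

    triplet: Triplet
    dot_scores: tuple[float, float, float]      # lncRNA, miRNA, mRNA
    edge_scores: tuple[float, float, float]     # lm, mm, ml
    influence_score: float
    S: float
    emp_p: float = np.nan
    n_case: int = 0
    n_control: int = 0

    def __post_init__(self) -> None:
        expected = float(sum(self.dot_scores) + sum(self.edge_scores) + self.influence_score)
        if not np.isclose(self.S, expected, rtol=0.0, atol=1e-9):
            raise ValueError(
                f"S={self.S} does not equal the sum of its components ({expected})"
            )


@dataclass
class DifferentialStats:
    """Per-gene case-vs-control log2 fold change and p-value for one RNA class."""

    table: pd.DataFrame  # index gene; columns log2FC, p
    rna_class: str

    def __post_init__(self) -> None:
        for col in ("log2FC", "p"):
            if col not in self.table.columns:
                raise FormatError(f"differential table lacks column {col!r}")
        p = self.table["p"].to_numpy(dtype=float)
        bad = (p <= 0) | (p > 1)
        if bad.any():
            gene = self.table.index[bad][0]
            raise FormatError(f"p-value outside (0, 1] for gene {gene!r}")
        if not np.isfinite(self.table["log2FC"].to_numpy(dtype=float)).all():
            raise FormatError("non-finite log2FC")
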
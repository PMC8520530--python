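"""Time-ordered background ceRNA network (TO-BCeN).

Genes are layered by multi-source breadth-first search from a small set of
initial nodes — the genes with the lowest mean dysregulation over the
triplets they participate in, taken from the intersection of the bottom
decile of two case conditions.  A gene's level is 1 + its graph distance to
the initial set; a triplet is assigned the minimum level among its three
members and appears at that level only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import Triplet
from .discovery import BackgroundNetwork


def node_dysregulation(scores: pd.DataFrame) -> pd.Series:
    """Per-gene mean of S over the triplets the gene participates in.

    ``scores`` is a score frame with lncRNA/miRNA/mRNA/S columns
    (see :func:`cernet.scoring.score_condition`).
    """
    if scores.empty:
        raise ValueError("no scored triplets")
    long = pd.concat([
        scores[["lncRNA", "S"]].rename(columns={"lncRNA": "gene"}),
        scores[["miRNA", "S"]].rename(columns={"miRNA": "gene"}),
        scores[["mRNA", "S"]].rename(columns={"mRNA": "gene"}),
    ])
    return long.groupby("gene")["S"].mean().sort_index()


def select_initial_nodes(node_scores_a: pd.Series,
                         node_scores_b: pd.Series | None = None,
                         decile: float = 0.10, k: int = 2) -> list[str]:
    """Initial nodes: lowest-score genes common to both conditions' bottom decile.

    The bottom ``decile`` fraction (at least one gene) of each condition is
    intersected; the ``k`` genes with smallest mean score are returned, ties
    broken lexicographically.  With a single condition the bottom decile of
    that condition alone is used.
    """
    if not 0.0 < decile < 1.0:
        raise ValueError(f"decile must lie in (0, 1), got {decile}")
    if k < 1:
        raise ValueError("k must be >= 1")

    def bottom(s: pd.Series) -> set[str]:
        m = max(1, int(np.ceil(decile * len(s))))
        return set(s.sort_values(kind="stable").index[:m])

    if node_scores_b is None:
        pool = bottom(node_scores_a)
        mean = node_scores_a
    else:
        pool = bottom(node_scores_a) & bottom(node_scores_b)
        if not pool:
            raise ValueError("bottom deciles of the two conditions do not intersect; "
                             "try a larger decile")
        mean = (node_scores_a.loc[sorted(pool)] + node_scores_b.loc[sorted(pool)]) / 2.0
    if k > len(pool):
        raise ValueError(f"k={k} exceeds the candidate pool of {len(pool)} genes")
    ordered = sorted(pool, key=lambda g: (mean.loc[g], g))
    return ordered[:k]


@dataclass
class TimeOrderedNetwork:
    initial_nodes: list[str]
    gene_level: dict[str, int]
    triplet_level: dict[tuple[str, str, str], int]
    n_levels: int
    unreachable: list[str] = field(default_factory=list)

    def triplets_at(self, level: int) -> list[tuple[str, str, str]]:
        return sorted(t for t, lv in self.triplet_level.items() if lv == level)

    def level_frame(self) -> pd.DataFrame:
        rows = [(l, m, y, lv) for (l, m, y), lv in sorted(self.triplet_level.items())]
        return pd.DataFrame(rows, columns=["lncRNA", "miRNA", "mRNA", "level"])

    def gene_frame(self) -> pd.DataFrame:
        rows = sorted(self.gene_level.items())
        return pd.DataFrame(rows, columns=["gene", "level"])


def build_tobcen(net: BackgroundNetwork, initial: list[str]) -> TimeOrderedNetwork:
    """Multi-source BFS layering: gene level = 1 + distance to the initial set;
    triplet level = min member level (the triplet is dropped from later
    levels, so each appears exactly once).  Genes unreachable from the
    initial set are put one level beyond the deepest reachable level and
    reported in ``unreachable``."""
    g = net.gene_graph
    missing = [v for v in initial if v not in g]
    if missing:
        raise ValueError(f"initial node {missing[0]!r} not in the background network")
    dist = nx.multi_source_dijkstra_path_length(g, set(initial), weight=None)
    reachable_max = max(dist.values())
    n_levels = reachable_max + 1
    gene_level = {v: d + 1 for v, d in dist.items()}
    unreachable = sorted(v for v in g.nodes if v not in dist)
    for v in unreachable:
        gene_level[v] = n_levels + 1
    triplet_level = {
        t.key: min(gene_level[t.lncrna], gene_level[t.mirna], gene_level[t.mrna])
        for t in net.triplets
    }
    total_levels = n_levels + (1 if unreachable else 0)
    return TimeOrderedNetwork(list(initial), gene_level, triplet_level,
                              total_levels, unreachable)


def map_triplets_to_levels(tobcen: TimeOrderedNetwork,
                           triplets: list[Triplet] | list[tuple[str, str, str]],
                           ) -> dict[tuple[str, str, str], int]:
    """Project (e.g. dysregulated) triplets onto an existing TO-BCeN by
    identity; triplets absent from the background network are dropped."""
    out = {}
    for t in triplets:
        key = t.key if isinstance(t, Triplet) else tuple(t)
        if key in tobcen.triplet_level:
            out[key] = tobcen.triplet_level[key]
    return out


@dataclass
class StabilityReport:
    """Per-replicate tabulation of triplet level changes vs the original
    ordering (new minus original; a move from L3 to L2 counts as -1)."""

    table: pd.DataFrame  # columns: initial_nodes, unchanged, cross1, cross2, multi, mean, sd

    def totals_ok(self, n_triplets: int) -> bool:
        s = self.table[["unchanged", "cross1", "cross2", "multi"]].sum(axis=1)
        return bool((s == n_triplets).all())


def tabulate_level_changes(original: dict[tuple, int], new: dict[tuple, int]) -> dict:
    """Histogram of per-triplet level changes between two orderings."""
    common = sorted(set(original) & set(new))
    delta = np.asarray([new[t] - original[t] for t in common], dtype=float)
    return {
        "unchanged": int((delta == 0).sum()),
        "cross1": int((np.abs(delta) == 1).sum()),
        "cross2": int((np.abs(delta) == 2).sum()),
        "multi": int((np.abs(delta) > 2).sum()),
        "mean": float(delta.mean()) if len(delta) else 0.0,
        "sd": float(delta.std(ddof=0)) if len(delta) else 0.0,
    }


def stability_analysis(net: BackgroundNetwork, original: TimeOrderedNetwork,
                       n_rep: int = 10, seed: int | np.random.Generator = 0,
                       level1_pool: list[str] | None = None,
                       n_initial: int = 2) -> StabilityReport:
    """Rebuild the TO-BCeN ``n_rep`` times from freshly sampled level-1 genes
    and tabulate how triplet levels move (Summary-of-level-order-changes
    procedure)."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if level1_pool is None:
        # genes of level-1 triplets (the triplet-based L1), excluding the
        # original initial nodes themselves
        pool_set: set[str] = set()
        for t in original.triplets_at(1):
            pool_set.update(t)
        pool_set -= set(original.initial_nodes)
        pool = sorted(pool_set)
    else:
        pool = sorted(level1_pool)
    if len(pool) < n_initial:
        raise ValueError(f"level-1 pool has {len(pool)} genes; need >= {n_initial}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for _ in range(n_rep):
        picks = sorted(rng.choice(pool, size=n_initial, replace=False).tolist())
        alt = build_tobcen(net, picks)
        h = tabulate_level_changes(original.triplet_level, alt.triplet_level)
        rows.append({"initial_nodes": ",".join(picks), **h})
    return StabilityReport(pd.DataFrame(rows))
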
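"""Level-wise comparison of two case conditions on a shared TO-BCeN.

Per level: counts of condition-specific and common dysregulated triplets
(proportion = |A ∩ B| / |A ∪ B|); per-sample level activity as the mean
z-scored log2(x + 1) expression of the level's member mRNAs (a light-weight
per-sample set-activity score standing in for heavier gene-set variation
methods — tagged ``mean_zscore`` in output metadata); Pearson correlation
between level activities and complete-linkage hierarchical clustering of
the correlation rows under Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .datatypes import ExpressionDataset

ACTIVITY_METHOD = "mean_zscore"


def common_triplet_stats(map_a: dict[tuple, int], map_b: dict[tuple, int]) -> pd.DataFrame:
    """Per-level common-triplet counts for two triplet->level maps.

    Both maps must come from the same TO-BCeN.  Proportion is
    |A ∩ B| / |A ∪ B| at that level (0 where the union is empty).
    """
    levels = sorted(set(map_a.values()) | set(map_b.values()))
    rows = []
    for lv in levels:
        a = {t for t, l in map_a.items() if l == lv}
        b = {t for t, l in map_b.items() if l == lv}
        union = a | b
        rows.append({
            "level": lv, "n_condA": len(a), "n_condB": len(b),
            "n_common": len(a & b),
            "proportion_common": len(a & b) / len(union) if union else 0.0,
        })
    return pd.DataFrame(rows)


def level_activity(ds: ExpressionDataset, triplet_level: dict[tuple, int],
                   level: int, classes: tuple[str, ...] = ("mRNA",)) -> pd.Series:
    """Per-sample activity of one level: mean across the level's member genes
    of z-scored (across samples) log2(x + 1) expression."""
    members: set[tuple[str, str]] = set()
    for (l, m, y), lv in triplet_level.items():
        if lv == level:
            members.update({("lncRNA", l), ("miRNA", m), ("mRNA", y)})
    rows = []
    for cls in classes:
        log = ds.log2(cls)
        for c, g in members:
            if c == cls and g in log.index:
                rows.append(log.loc[g])
    if not rows:
        raise ValueError(f"level {level} has no member genes of class {classes}")
    mat = pd.DataFrame(rows)
    mu = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=0)
    if (sd == 0).any():
        mat = mat.loc[sd > 0]
        if mat.empty:
            raise ValueError(f"level {level}: all member genes are constant")
        mu, sd = mu.loc[mat.index], sd.loc[mat.index]
    z = mat.sub(mu, axis=0).div(sd, axis=0)
    return z.mean(axis=0).rename(f"L{level}")


def level_activity_matrix(ds: ExpressionDataset, triplet_level: dict[tuple, int],
                          classes: tuple[str, ...] = ("mRNA",)) -> pd.DataFrame:
    """Levels x samples activity matrix over the populated levels (levels
    with no member of the requested classes are skipped)."""
    rows = []
    for lv in sorted(set(triplet_level.values())):
        try:
            rows.append(level_activity(ds, triplet_level, lv, classes))
        except ValueError:
            continue
    if not rows:
        raise ValueError("no level has members of the requested classes")
    out = pd.DataFrame(rows)
    out.attrs["method"] = ACTIVITY_METHOD
    return out


@dataclass
class LevelClustering:
    pcc: pd.DataFrame          # level x level Pearson correlations
    linkage_matrix: np.ndarray  # scipy linkage (complete, Euclidean on PCC rows)
    labels: list[str]

    def newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        trees = {i: self.labels[i] for i in range(n)}
        for k, (a, b, h, _cnt) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = h - heights[a]
            lb = h - heights[b]
            node = n + k
            trees[node] = f"({trees[a]}:{la:.6g},{trees[b]}:{lb:.6g})"
            heights[node] = h
        return trees[n + len(self.linkage_matrix) - 1] + ";"


def cluster_levels(activity: pd.DataFrame) -> LevelClustering:
    """Pearson correlation between level activity vectors, then complete
    linkage on the Euclidean distances between PCC rows.  A constant
    activity vector makes its correlations undefined and is rejected."""
    if activity.shape[0] < 2:
        raise ValueError("need at least two levels to cluster")
    sd = activity.std(axis=1, ddof=0)
    if (sd == 0).any():
        lvl = activity.index[sd == 0][0]
        raise ValueError(f"activity of level {lvl!r} is constant; PCC undefined")
    pcc = activity.T.corr(method="pearson")
    z = linkage(pdist(pcc.to_numpy(), metric="euclidean"), method="complete")
    return LevelClustering(pcc, z, [str(i) for i in activity.index])
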
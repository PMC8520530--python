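"""Discovery of ceRNA triplets in control samples.

A (lncRNA, miRNA, mRNA) triplet is emitted when

* the lncRNA and mRNA share a significant number of miRNA interactors
  (one-sided upper-tail hypergeometric test within the expressed-miRNA
  universe, p < ``hyper_p``);
* the control-sample Pearson correlations satisfy
  lncRNA-mRNA > 0.7, miRNA-mRNA < -0.7, miRNA-lncRNA < -0.7, each with a
  two-sided p < 0.05 (correlations on log2(x + 1) values);
* the (miRNA, mRNA) and (miRNA, lncRNA) pairs are curated interactions.

The union of all emitted triplets' pairwise edges forms an undirected gene
graph; the triplets whose three members all lie in its largest connected
component constitute the background ceRNA network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .datatypes import ExpressionDataset, InteractionSet, Triplet


def shared_mirna_test(lncrna_mirnas: set[str], mrna_mirnas: set[str],
                      universe: set[str]) -> float:
    """Upper-tail hypergeometric p for the overlap of two miRNA interactor sets.

    With a universe of N miRNAs, of which the lncRNA interacts with K and the
    mRNA with n, the p-value is P(X >= observed overlap) for
    X ~ Hypergeometric(N, K, n).  An overlap of 0 yields p = 1.
    """
    if not universe:
        raise ValueError("empty miRNA universe")
    a = lncrna_mirnas & universe
    b = mrna_mirnas & universe
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(a), len(b)))


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided t-based p-value (n > 3 required).

    Perfect correlations are clipped to +/-0.999999 before the t transform so
    the p-value stays finite.
    """
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 observations for a correlation p-value, got {n}")
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x, y)[0, 1]
    if not np.isfinite(r):  # constant vector
        return np.nan, 1.0
    rc = float(np.clip(r, -0.999999, 0.999999))
    t = rc * np.sqrt((n - 2) / (1.0 - rc * rc))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return float(r), float(p)


def _corr_and_p(a: np.ndarray, b: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise correlation of matrix a rows against matched matrix b rows."""
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((az * az).sum(axis=1) * (bz * bz).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (az * bz).sum(axis=1) / denom
    rc = np.clip(r, -0.999999, 0.999999)
    t = rc * np.sqrt((n - 2) / (1.0 - rc * rc))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isfinite(r), p, 1.0)
    return r, p


def discover_triplets(ds: ExpressionDataset, interactions: InteractionSet,
                      cfg: PipelineConfig | None = None,
                      control_group: str = "control") -> list[Triplet]:
    """Identify ceRNA triplets from control samples.

    ``ds`` may contain case samples as well; only the ``control_group``
    columns are used.  Candidate lncRNA-mRNA pairs are those sharing at
    least one expressed miRNA interactor.  Output order is deterministic
    (sorted by (lncRNA, miRNA, mRNA)) and invariant to input row order.
    """
    cfg = cfg or PipelineConfig()
    control = ds.samples_of(control_group) if control_group in set(ds.sample_groups) else ds.samples
    if len(control) < 4:
        raise ValueError(f"need >= 4 control samples, got {len(control)}")
    n = len(control)

    log_l = ds.lncrna[control].pipe(lambda d: np.log2(d + 1.0))
    log_m = ds.mirna[control].pipe(lambda d: np.log2(d + 1.0))
    log_y = ds.mrna[control].pipe(lambda d: np.log2(d + 1.0))

    expressed_mirnas = set(log_m.index)
    # universe: expressed miRNAs carrying at least one curated interaction
    universe = {m for m in interactions.mirnas() if m in expressed_mirnas}
    if not universe:
        raise ValueError("no expressed miRNA has a curated interaction")

    mirnas_of_lnc: dict[str, set[str]] = {}
    for m, l in interactions.mirna_lncrna:
        if m in universe and l in log_l.index:
            mirnas_of_lnc.setdefault(l, set()).add(m)
    mirnas_of_mrna: dict[str, set[str]] = {}
    for m, y in interactions.mirna_mrna:
        if m in universe and y in log_y.index:
            mirnas_of_mrna.setdefault(y, set()).add(m)

    # candidate pairs share >= 1 miRNA interactor
    lnc_of_mirna: dict[str, set[str]] = {}
    for l, ms in mirnas_of_lnc.items():
        for m in ms:
            lnc_of_mirna.setdefault(m, set()).add(l)
    candidates: dict[tuple[str, str], set[str]] = {}
    for y, ms in mirnas_of_mrna.items():
        for m in ms:
            for l in lnc_of_mirna.get(m, ()):
                candidates.setdefault((l, y), set()).add(m)

    triplets: list[Triplet] = []
    for (l, y) in sorted(candidates):
        hyper_p = shared_mirna_test(mirnas_of_lnc[l], mirnas_of_mrna[y], universe)
        if not hyper_p < cfg.hyper_p:
            continue
        lv = log_l.loc[l].to_numpy()
        yv = log_y.loc[y].to_numpy()
        r_lm, p_lm = pearson_with_p(lv, yv)
        if not (r_lm > cfg.pcc_pos and p_lm < cfg.pcc_p):
            continue
        for m in sorted(candidates[(l, y)]):
            mv = log_m.loc[m].to_numpy()
            r_mm, p_mm = pearson_with_p(mv, yv)
            if not (r_mm < cfg.pcc_neg and p_mm < cfg.pcc_p):
                continue
            r_ml, p_ml = pearson_with_p(mv, lv)
            if not (r_ml < cfg.pcc_neg and p_ml < cfg.pcc_p):
                continue
            triplets.append(Triplet(
                lncrna=l, mirna=m, mrna=y, shared_mirna_p=hyper_p,
                pcc_lm=r_lm, pcc_mm=r_mm, pcc_ml=r_ml,
                pcc_ps=(p_lm, p_mm, p_ml),
            ))
    triplets.sort(key=lambda t: t.key)
    return triplets


@dataclass
class BackgroundNetwork:
    """Triplets of the largest connected component plus their gene graph."""

    triplets: list[Triplet]
    gene_graph: nx.Graph = field(repr=False)

    def genes(self) -> set[str]:
        return set(self.gene_graph.nodes)

    def neighbors_by_class(self, gene: str, classes: set[str]) -> set[str]:
        return {v for v in self.gene_graph.neighbors(gene)
                if self.gene_graph.nodes[v]["rna_class"] in classes}

    def nodes_of_class(self, classes: set[str]) -> set[str]:
        return {v for v, d in self.gene_graph.nodes(data=True)
                if d["rna_class"] in classes}


def build_gene_graph(triplets: list[Triplet]) -> nx.Graph:
    g = nx.Graph()
    for t in triplets:
        g.add_node(t.lncrna, rna_class="lncRNA")
        g.add_node(t.mirna, rna_class="miRNA")
        g.add_node(t.mrna, rna_class="mRNA")
        g.add_edge(t.lncrna, t.mrna)
        g.add_edge(t.mirna, t.mrna)
        g.add_edge(t.mirna, t.lncrna)
    return g


def largest_component(triplets: list[Triplet]) -> BackgroundNetwork:
    """Background ceRNA network: triplets whose genes all lie in the largest
    connected component of the union gene graph.

    Component ties are broken by node count, then edge count, then the
    lexicographically smallest member id.
    """
    if not triplets:
        raise ValueError("no triplets supplied")
    g = build_gene_graph(triplets)
    comps = list(nx.connected_components(g))
    comps.sort(key=lambda c: (-len(c), -g.subgraph(c).number_of_edges(), min(c)))
    keep = comps[0]
    kept = [t for t in triplets if set(t.genes) <= keep]
    return BackgroundNetwork(kept, g.subgraph(keep).copy())
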
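"""Composite dysregulated score S of a ceRNA triplet and its permutation p.

S combines, per triplet and case condition:

* three **node (dot) scores** — the CDF of z = (-log10 p) * |log2FC| under
  the product model Z = E * |N|, E ~ Exponential(rate ln 10),
  N ~ Normal(0, sigma^2), where sigma^2 is the variance of log2FC across all
  genes of the member's RNA class:

      F_Z(z) = 1 - sqrt(2 / (pi sigma^2)) *
               integral_0^inf exp(-(x^2 / (2 sigma^2) + ln10 * z / x)) dx

* three **edge scores** — differential correlation of each triplet pair,
  Phi(Y * [F(r_case) - F(r_control)] / sigma_d) with F the Fisher z
  transform, Y = +1 when r_control < 0 (else -1) and
  sigma_d^2 = 1/(n_case - 3) + 1/(n_control - 3), the null sampling variance
  of a Fisher-z difference;

* an **influence score** — for each member, 1 minus the one-sided Fisher
  exact p for enrichment of its background-network neighbours in SDE genes
  (miRNA neighbours for the lncRNA and the mRNA; mRNA+lncRNA neighbours for
  the miRNA), summed over the three members.

Significance is assessed by shuffling the case/control sample labels
(jointly across the three RNA classes, preserving group sizes), recomputing
S, and reporting the fraction of permuted scores strictly greater than the
observed one.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.interpolate import PchipInterpolator
from scipy.special import ndtr

from .config import PipelineConfig
from .datatypes import DifferentialStats, ExpressionDataset, Triplet, TripletScore
from .diffexpr import welch_log_ttest
from .discovery import BackgroundNetwork

LAMBDA = float(np.log(10.0))


# -- node (dot) score ----------------------------------------------------

def _dot_kernel(w: float) -> float:
    """G(w) = sqrt(2/pi) * int_0^inf exp(-t^2/2 - w/t) dt, so that the node
    score is 1 - G(ln10 * z / sigma).  Adaptive quadrature, abs tol 1e-10."""
    if w < 0:
        raise ValueError(f"kernel argument must be >= 0, got {w}")
    if w == 0.0:
        return 1.0
    val, _ = integrate.quad(
        lambda t: np.exp(-0.5 * t * t - w / t), 0.0, np.inf,
        epsabs=1e-12, epsrel=1e-10, limit=300,
    )
    return float(np.sqrt(2.0 / np.pi) * val)


_KERNEL_TABLE: PchipInterpolator | None = None
_KERNEL_W_MIN, _KERNEL_W_MAX = 1e-8, 400.0


def _kernel_table() -> PchipInterpolator:
    """Monotone interpolant of G on a dense log grid (built once; max abs
    deviation from quadrature ~1e-9, used by the vectorised engine)."""
    global _KERNEL_TABLE
    if _KERNEL_TABLE is None:
        w = np.geomspace(_KERNEL_W_MIN, _KERNEL_W_MAX, 1500)
        g = np.array([_dot_kernel(x) for x in w])
        _KERNEL_TABLE = PchipInterpolator(np.log(w), g, extrapolate=False)
    return _KERNEL_TABLE


def _dot_from_w(w: np.ndarray) -> np.ndarray:
    tab = _kernel_table()
    w = np.asarray(w, dtype=float)
    g = np.ones_like(w)
    mid = (w > _KERNEL_W_MIN) & (w < _KERNEL_W_MAX)
    g[mid] = tab(np.log(w[mid]))
    g[w >= _KERNEL_W_MAX] = 0.0
    return np.clip(1.0 - g, 0.0, 1.0)


def dot_score(p: float, log2fc: float, sigma2: float) -> float:
    """Node score F_Z((-log10 p) * |log2fc|) with class FC-variance sigma2.

    Exact-quadrature scalar form; F_Z(0) = 0 and F_Z -> 1 as z grows.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    if sigma2 <= 0.0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    z = (-np.log10(p)) * abs(log2fc)
    w = LAMBDA * z / np.sqrt(sigma2)
    return float(np.clip(1.0 - _dot_kernel(w), 0.0, 1.0))


# -- edge score ----------------------------------------------------------

def fisher_z(r: float) -> float:
    """Fisher transform F(r) = 0.5 * ln((1 + r) / (1 - r)); |r| must be < 1."""
    if not -1.0 < r < 1.0:
        raise ValueError(f"|r| must be < 1 for the Fisher transform, got {r}")
    return float(0.5 * np.log((1.0 + r) / (1.0 - r)))


_R_CLIP = 0.999999


def edge_score(r_case: float, r_control: float, n_case: int, n_control: int) -> float:
    """Differential-correlation edge score in (0, 1); 0.5 when r_case equals
    r_control.  Larger values mean the case correlation moved further away
    from the control correlation (in the direction of correlation loss)."""
    if n_case <= 3 or n_control <= 3:
        raise ValueError("need more than 3 samples per group for a Fisher-z variance")
    y = -1.0 if r_control > 0 else 1.0
    d = y * (fisher_z(float(np.clip(r_case, -_R_CLIP, _R_CLIP)))
             - fisher_z(float(np.clip(r_control, -_R_CLIP, _R_CLIP))))
    sigma = np.sqrt(1.0 / (n_case - 3) + 1.0 / (n_control - 3))
    return float(ndtr(d / sigma))


# -- influence score -----------------------------------------------------

def influence_component(neighbors: set[str], sde: set[str], universe: set[str]) -> float:
    """1 - p of the one-sided (enrichment) Fisher exact test on the 2x2 table
    {neighbour vs non-neighbour} x {SDE vs not} within ``universe``.

    A focal gene with no neighbours contributes 0 (p taken as 1).
    """
    if not set(neighbors) <= set(universe) or not set(sde) <= set(universe):
        raise ValueError("neighbors and sde must be subsets of the universe")
    n = len(neighbors)
    if n == 0:
        return 0.0
    M = len(universe)
    K = len(sde)
    k = len(set(neighbors) & set(sde))
    p = float(stats.hypergeom.sf(k - 1, M, K, n))
    return 1.0 - p


# -- vectorised scoring engine ------------------------------------------

class _InfluenceBlock:
    """Neighbour bookkeeping for one influence component (fixed under
    permutation: only the SDE calls change)."""

    def __init__(self, focal_genes: Sequence[str], net: BackgroundNetwork,
                 neighbor_classes: set[str], universe_rows: list[tuple[str, int]]):
        # universe_rows: (class, row-index) per universe gene, in fixed order
        pos = {}
        self.universe_rows = universe_rows
        for i, (gene, _cls, _row) in enumerate(universe_rows):
            pos[gene] = i
        flat: list[int] = []
        offsets = [0]
        degs = []
        for gene in focal_genes:
            nbrs = sorted(net.neighbors_by_class(gene, neighbor_classes))
            nbrs = [v for v in nbrs if v in pos]
            flat.extend(pos[v] for v in nbrs)
            degs.append(len(nbrs))
            offsets.append(len(flat))
        self.flat = np.asarray(flat, dtype=np.intp)
        self.offsets = np.asarray(offsets, dtype=np.intp)
        self.deg = np.asarray(degs, dtype=np.intp)
        self.M = len(universe_rows)

    def scores(self, sde_univ: np.ndarray) -> np.ndarray:
        """1 - hypergeometric enrichment p per focal gene given the boolean
        SDE vector over the universe."""
        K = int(sde_univ.sum())
        hits = sde_univ[self.flat].astype(np.int64) if len(self.flat) else np.empty(0, np.int64)
        cs = np.concatenate([[0], np.cumsum(hits)])
        k = cs[self.offsets[1:]] - cs[self.offsets[:-1]]
        out = np.zeros(len(self.deg))
        nz = self.deg > 0
        if nz.any():
            p = stats.hypergeom.sf(k[nz] - 1, self.M, K, self.deg[nz])
            out[nz] = 1.0 - p
        return out


class ScoringEngine:
    """Computes all triplet scores for one case-vs-control comparison, and
    re-computes them under permuted sample labels.

    All genes of the filtered dataset define the FC-variance and SDE
    universes of their RNA class; influence neighbourhoods come from the
    background network.
    """

    def __init__(self, triplets: Sequence[Triplet], ds: ExpressionDataset,
                 case: str, control: str, net: BackgroundNetwork,
                 cfg: PipelineConfig | None = None):
        self.cfg = cfg or PipelineConfig()
        self.triplets = list(triplets)
        case_samples = ds.samples_of(case)
        control_samples = ds.samples_of(control)
        if len(case_samples) <= 3 or len(control_samples) <= 3:
            raise ValueError("need more than 3 samples in both case and control groups")
        self.n_case, self.n_control = len(case_samples), len(control_samples)
        samples = case_samples + control_samples

        self.log = {c: ds.log2(c)[samples].to_numpy() for c in ("mRNA", "miRNA", "lncRNA")}
        self.gene_index = {c: {g: i for i, g in enumerate(ds.matrix(c).index)}
                           for c in ("mRNA", "miRNA", "lncRNA")}
        self.case_cols = np.arange(self.n_case)
        self.control_cols = np.arange(self.n_case, self.n_case + self.n_control)

        def rows(cls: str, genes: list[str]) -> np.ndarray:
            idx = self.gene_index[cls]
            missing = [g for g in genes if g not in idx]
            if missing:
                raise KeyError(f"no {cls} expression for gene {missing[0]!r}")
            return np.asarray([idx[g] for g in genes], dtype=np.intp)

        self.l_rows = rows("lncRNA", [t.lncrna for t in self.triplets])
        self.m_rows = rows("miRNA", [t.mirna for t in self.triplets])
        self.y_rows = rows("mRNA", [t.mrna for t in self.triplets])

        # influence blocks: unique focal genes per role, mapped back per triplet
        def universe_rows(classes: tuple[str, ...]) -> list[tuple[str, str, int]]:
            out = []
            for cls in classes:
                idx = self.gene_index[cls]
                for g in sorted(net.nodes_of_class({cls})):
                    if g in idx:
                        out.append((g, cls, idx[g]))
            return out

        self._univ = {
            "miRNA": universe_rows(("miRNA",)),
            "mRNA+lncRNA": universe_rows(("mRNA", "lncRNA")),
        }
        uniq_l = sorted({t.lncrna for t in self.triplets})
        uniq_m = sorted({t.mirna for t in self.triplets})
        uniq_y = sorted({t.mrna for t in self.triplets})
        self._blk_l = _InfluenceBlock(uniq_l, net, {"miRNA"}, self._univ["miRNA"])
        self._blk_m = _InfluenceBlock(uniq_m, net, {"mRNA", "lncRNA"}, self._univ["mRNA+lncRNA"])
        self._blk_y = _InfluenceBlock(uniq_y, net, {"miRNA"}, self._univ["miRNA"])
        self._map_l = np.asarray([uniq_l.index(t.lncrna) for t in self.triplets], dtype=np.intp)
        self._map_m = np.asarray([uniq_m.index(t.mirna) for t in self.triplets], dtype=np.intp)
        self._map_y = np.asarray([uniq_y.index(t.mrna) for t in self.triplets], dtype=np.intp)
        _kernel_table()  # build once up front

    # -- helpers --------------------------------------------------------
    @staticmethod
    def _row_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        az = a - a.mean(axis=1, keepdims=True)
        bz = b - b.mean(axis=1, keepdims=True)
        denom = np.sqrt((az * az).sum(axis=1) * (bz * bz).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (az * bz).sum(axis=1) / denom
        return np.nan_to_num(r, nan=0.0)

    def _de(self, mat: np.ndarray, case_cols: np.ndarray, control_cols: np.ndarray):
        return welch_log_ttest(mat[:, case_cols], mat[:, control_cols])

    def _dots(self, p: np.ndarray, fc: np.ndarray) -> tuple[np.ndarray, float]:
        sigma2 = float(np.var(fc, ddof=1)) if len(fc) > 1 else 0.0
        if sigma2 <= 0.0:
            return np.zeros_like(fc), sigma2
        z = (-np.log10(p)) * np.abs(fc)
        w = LAMBDA * z / np.sqrt(sigma2)
        return _dot_from_w(w), sigma2

    def _edge(self, r_case: np.ndarray, r_control: np.ndarray) -> np.ndarray:
        y = np.where(r_control > 0, -1.0, 1.0)
        d = y * (np.arctanh(np.clip(r_case, -_R_CLIP, _R_CLIP))
                 - np.arctanh(np.clip(r_control, -_R_CLIP, _R_CLIP)))
        sigma = np.sqrt(1.0 / (self.n_case - 3) + 1.0 / (self.n_control - 3))
        return ndtr(d / sigma)

    # -- one full evaluation --------------------------------------------
    def evaluate(self, case_cols: np.ndarray | None = None,
                 control_cols: np.ndarray | None = None,
                 class_cols: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
                 de_override: dict[str, DifferentialStats] | None = None) -> dict:
        """Score every triplet for one assignment of samples to groups.

        ``class_cols`` (per-RNA-class column splits) supports the alternative
        per-class shuffle; by default all classes share one split.
        """
        if class_cols is None:
            cc = case_cols if case_cols is not None else self.case_cols
            oc = control_cols if control_cols is not None else self.control_cols
            class_cols = {c: (cc, oc) for c in ("mRNA", "miRNA", "lncRNA")}

        de: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for cls in ("mRNA", "miRNA", "lncRNA"):
            if de_override is not None and cls in de_override:
                tab = de_override[cls].table.reindex(
                    [g for g, _ in sorted(self.gene_index[cls].items(), key=lambda kv: kv[1])]
                )
                fc = tab["log2FC"].to_numpy(dtype=float)
                p = tab["p"].to_numpy(dtype=float)
                if np.isnan(p).any():
                    raise ValueError(f"external DE table lacks genes of class {cls}")
            else:
                fc, p = self._de(self.log[cls], *class_cols[cls])
            de[cls] = (fc, p)

        dots = {}
        sigma2 = {}
        for cls in ("mRNA", "miRNA", "lncRNA"):
            dots[cls], sigma2[cls] = self._dots(de[cls][1], de[cls][0])

        dot_l = dots["lncRNA"][self.l_rows]
        dot_m = dots["miRNA"][self.m_rows]
        dot_y = dots["mRNA"][self.y_rows]

        def pair_r(cls_a: str, rows_a: np.ndarray, cls_b: str, rows_b: np.ndarray,
                   which: int) -> np.ndarray:
            # which: 0 -> case columns, 1 -> control columns; inter-class pairs
            # use each class's own column split (identical under shared shuffle)
            a = self.log[cls_a][rows_a][:, class_cols[cls_a][which]]
            b = self.log[cls_b][rows_b][:, class_cols[cls_b][which]]
            return self._row_corr(a, b)

        e_lm = self._edge(pair_r("lncRNA", self.l_rows, "mRNA", self.y_rows, 0),
                          pair_r("lncRNA", self.l_rows, "mRNA", self.y_rows, 1))
        e_mm = self._edge(pair_r("miRNA", self.m_rows, "mRNA", self.y_rows, 0),
                          pair_r("miRNA", self.m_rows, "mRNA", self.y_rows, 1))
        e_ml = self._edge(pair_r("miRNA", self.m_rows, "lncRNA", self.l_rows, 0),
                          pair_r("miRNA", self.m_rows, "lncRNA", self.l_rows, 1))

        thr_p, thr_fc = self.cfg.sde_p, self.cfg.sde_fc
        sde = {cls: (de[cls][1] < thr_p) & (np.abs(de[cls][0]) > thr_fc)
               for cls in ("mRNA", "miRNA", "lncRNA")}
        sde_mir_univ = np.asarray([sde["miRNA"][row] for _, _, row in self._univ["miRNA"]],
                                  dtype=bool)
        sde_my_univ = np.asarray([sde[cls][row] for _, cls, row in self._univ["mRNA+lncRNA"]],
                                 dtype=bool)
        is_l = self._blk_l.scores(sde_mir_univ)[self._map_l]
        is_m = self._blk_m.scores(sde_my_univ)[self._map_m]
        is_y = self._blk_y.scores(sde_mir_univ)[self._map_y]
        infl = is_l + is_m + is_y

        S = dot_l + dot_m + dot_y + e_lm + e_mm + e_ml + infl
        return {
            "dot": np.column_stack([dot_l, dot_m, dot_y]),
            "edge": np.column_stack([e_lm, e_mm, e_ml]),
            "influence": infl,
            "S": S,
            "sigma2": sigma2,
        }

    # -- permutation null ------------------------------------------------
    def permutation_pvalues(self, S_obs: np.ndarray, n_perm: int,
                            seed: int | np.random.Generator = 0) -> np.ndarray:
        """Empirical p per triplet: #(S_random > S_obs) / n_perm, strict.

        Case/control labels are reshuffled per permutation (group sizes
        preserved); with ``shuffle_mode='shared'`` one shuffle is applied to
        all three RNA classes, with ``'per_rna'`` each class is shuffled
        independently.  SDE calls are recomputed per permutation.
        """
        if n_perm < 100:
            raise ValueError(f"n_perm must be >= 100, got {n_perm}")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        n_tot = self.n_case + self.n_control
        exceed = np.zeros(len(self.triplets), dtype=np.int64)
        for _ in range(n_perm):
            if self.cfg.shuffle_mode == "shared":
                perm = rng.permutation(n_tot)
                split = {c: (perm[:self.n_case], perm[self.n_case:])
                         for c in ("mRNA", "miRNA", "lncRNA")}
            else:
                split = {}
                for c in ("mRNA", "miRNA", "lncRNA"):
                    perm = rng.permutation(n_tot)
                    split[c] = (perm[:self.n_case], perm[self.n_case:])
            S_rand = self.evaluate(class_cols=split)["S"]
            exceed += S_rand > S_obs
        return exceed / float(n_perm)


# -- high-level API ------------------------------------------------------

def score_triplets(triplets: Sequence[Triplet], ds: ExpressionDataset,
                   case: str, control: str, net: BackgroundNetwork,
                   cfg: PipelineConfig | None = None,
                   de_override: dict[str, DifferentialStats] | None = None,
                   ) -> list[TripletScore]:
    """Observed composite scores (no permutation p yet)."""
    engine = ScoringEngine(triplets, ds, case, control, net, cfg)
    res = engine.evaluate(de_override=de_override)
    out = []
    for i, t in enumerate(triplets):
        out.append(TripletScore(
            triplet=t,
            dot_scores=tuple(res["dot"][i]),
            edge_scores=tuple(res["edge"][i]),
            influence_score=float(res["influence"][i]),
            S=float(res["S"][i]),
            n_case=engine.n_case, n_control=engine.n_control,
        ))
    return out


def score_condition(triplets: Sequence[Triplet], ds: ExpressionDataset,
                    case: str, control: str, net: BackgroundNetwork,
                    cfg: PipelineConfig | None = None,
                    seed: int | None = None,
                    de_override: dict[str, DifferentialStats] | None = None,
                    ) -> pd.DataFrame:
    """Score all triplets for one case condition and attach empirical p.

    Returns a tidy frame with one row per triplet: the three dot scores,
    three edge scores, influence score, S, emp_p and the dysregulated flag
    (emp_p < cfg.dysreg_p).
    """
    cfg = cfg or PipelineConfig()
    engine = ScoringEngine(triplets, ds, case, control, net, cfg)
    obs = engine.evaluate(de_override=de_override)
    emp_p = engine.permutation_pvalues(
        obs["S"], cfg.n_perm, cfg.rng_seed if seed is None else seed)
    df = pd.DataFrame({
        "lncRNA": [t.lncrna for t in triplets],
        "miRNA": [t.mirna for t in triplets],
        "mRNA": [t.mrna for t in triplets],
        "dot_lncRNA": obs["dot"][:, 0], "dot_miRNA": obs["dot"][:, 1],
        "dot_mRNA": obs["dot"][:, 2],
        "edge_lm": obs["edge"][:, 0], "edge_mm": obs["edge"][:, 1],
        "edge_ml": obs["edge"][:, 2],
        "influence": obs["influence"],
        "S": obs["S"],
        "emp_p": emp_p,
    })
    df["dysregulated"] = df["emp_p"] < cfg.dysreg_p
    return df
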
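"""Synthetic expression and interaction data with planted ceRNA triplets.

The generator emulates a sample-matched three-class RNA-seq study of one
control and two case groups (default 8/8/8 samples, the scale of a small
myocardial biopsy cohort).  Expression is log-normal: log2 values are drawn
from Gaussians and exponentiated to positive TPM/RPM-like values, so the
pipeline's log2(x + 1) transform recovers the Gaussian scale exactly.

Planted triplets load on one latent ceRNA factor u per sample: lncRNA and
mRNA log values load +sqrt(r), the miRNA loads -sqrt(r), so every
within-triplet pair has population correlation exactly +r or -r (default
r = 0.9).  The shared factor mirrors the dense crosstalk of real ceRNA
networks: cross-triplet lncRNA/mRNA pairs are also correlated, and the
curated interaction set adds "bridge" shared-miRNA profiles between
consecutive triplets so that the emitted background network forms a single
large component rather than isolated 3-gene cliques.  Each candidate
lncRNA/mRNA pair shares a few extra decoy miRNAs (so the shared-miRNA
hypergeometric test has signal); random background edges are sprinkled on
top.

In case groups, a configurable fraction of planted triplets is dysregulated:
their correlations are broken (independent redraw) and their lncRNA/mRNA
means shifted up and miRNA mean shifted down by ``de_shift`` log2 units, so
node, edge and influence scores all receive signal.  Both mechanisms can be
toggled to test score components in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, InteractionSet


@dataclass
class SimulationConfig:
    n_control: int = 8
    n_caseA: int = 8
    n_caseB: int = 8
    n_mrna: int = 200
    n_mirna: int = 200
    n_lncrna: int = 60
    n_planted_triplets: int = 30
    r_cerna: float = 0.9           # target |correlation| inside planted triplets
    dysreg_fraction: float = 0.5   # fraction of planted triplets broken per case
    de_shift: float = 2.0          # log2 shift of dysregulated members in cases
    noise_sd: float = 1.0          # log2-scale SD of every gene
    log_mean: float = 8.0          # log2-scale mean expression
    n_shared_extra: int = 5        # extra miRNAs shared by each planted pair
    background_edge_density: float = 0.005
    break_correlation: bool = True
    shift_means: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.7 < self.r_cerna < 1.0:
            raise ValueError(f"r_cerna must lie in (0.7, 1), got {self.r_cerna}")
        for name in ("n_control", "n_caseA", "n_caseB", "n_mrna", "n_mirna",
                     "n_lncrna", "n_planted_triplets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dysreg_fraction <= 1.0:
            raise ValueError("dysreg_fraction must lie in [0, 1]")
        if self.n_planted_triplets > min(self.n_mrna, self.n_mirna, self.n_lncrna):
            raise ValueError("more planted triplets than genes of some class")


@dataclass
class GroundTruth:
    planted: list[tuple[str, str, str]]
    dysregulated: dict[str, list[tuple[str, str, str]]]  # group -> triplets

    def frame(self) -> pd.DataFrame:
        rows = []
        for t in self.planted:
            rows.append({
                "lncRNA": t[0], "miRNA": t[1], "mRNA": t[2],
                **{f"dysregulated_{g}": t in ts for g, ts in self.dysregulated.items()},
            })
        return pd.DataFrame(rows)


def triplet_correlation_matrix(r: float) -> np.ndarray:
    """Correlation of (lncRNA, miRNA, mRNA) log values: +r between lncRNA and
    mRNA, -r between the miRNA and each.  Positive definite for r < 1."""
    c = np.array([
        [1.0, -r, r],
        [-r, 1.0, -r],
        [r, -r, 1.0],
    ])
    eig = np.linalg.eigvalsh(c)
    if eig.min() <= 0:
        raise ValueError(f"correlation matrix not positive definite (r={r})")
    return c


def _expr(log_values: np.ndarray) -> np.ndarray:
    """Map log2-scale values to non-negative expression: x = 2^g - 1, clipped
    at zero so log2(x + 1) round-trips (negative g is vanishingly rare at the
    default mean)."""
    return np.maximum(2.0 ** np.maximum(log_values, 0.0) - 1.0, 0.0)


def simulate(cfg: SimulationConfig | None = None,
             ) -> tuple[ExpressionDataset, InteractionSet, GroundTruth]:
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    P = cfg.n_planted_triplets
    mrna_ids = [f"MRNA{i:04d}" for i in range(cfg.n_mrna)]
    mirna_ids = [f"MIR{i:04d}" for i in range(cfg.n_mirna)]
    lnc_ids = [f"LNC{i:04d}" for i in range(cfg.n_lncrna)]
    planted = [(lnc_ids[i], mirna_ids[i], mrna_ids[i]) for i in range(P)]
    triplet_correlation_matrix(cfg.r_cerna)  # PSD assertion

    n_dys = int(round(cfg.dysreg_fraction * P))
    dysA = planted[:n_dys]
    # caseB shares about half its dysregulated set with caseA (offset window)
    off = n_dys // 2
    dysB = planted[off:off + n_dys] if off + n_dys <= P else planted[P - n_dys:]

    groups = (["control"] * cfg.n_control + ["caseA"] * cfg.n_caseA
              + ["caseB"] * cfg.n_caseB)
    samples = [f"S{i:02d}" for i in range(len(groups))]
    group_of = pd.Series(groups, index=samples, name="group")

    a = np.sqrt(cfg.r_cerna)      # factor loading; pairwise corr = a^2 = r
    b = np.sqrt(1.0 - cfg.r_cerna)
    log_m = pd.DataFrame(0.0, index=mrna_ids, columns=samples)
    log_mi = pd.DataFrame(0.0, index=mirna_ids, columns=samples)
    log_l = pd.DataFrame(0.0, index=lnc_ids, columns=samples)

    def fill_group(cols: list[str], dys: set[tuple[str, str, str]]) -> None:
        n = len(cols)
        u = rng.standard_normal(n)  # shared ceRNA factor for this group
        for t in planted:
            l_id, mi_id, m_id = t
            eps = rng.standard_normal((3, n))
            if t in dys and cfg.break_correlation:
                z = eps  # independent: correlation with the factor broken
            else:
                z = np.vstack([a * u + b * eps[0],    # lncRNA
                               -a * u + b * eps[1],   # miRNA
                               a * u + b * eps[2]])   # mRNA
            g = cfg.log_mean + cfg.noise_sd * z
            if t in dys and cfg.shift_means:
                g[0] += cfg.de_shift   # lncRNA up
                g[1] -= cfg.de_shift   # miRNA down
                g[2] += cfg.de_shift   # mRNA up
            log_l.loc[l_id, cols] = g[0]
            log_mi.loc[mi_id, cols] = g[1]
            log_m.loc[m_id, cols] = g[2]
        # background genes: independent noise, identical law in all groups
        for frame, ids in ((log_m, mrna_ids), (log_mi, mirna_ids), (log_l, lnc_ids)):
            bg = ids[P:]
            frame.loc[bg, cols] = (cfg.log_mean
                                   + cfg.noise_sd * rng.standard_normal((len(bg), n)))

    ctrl_cols = samples[:cfg.n_control]
    a_cols = samples[cfg.n_control:cfg.n_control + cfg.n_caseA]
    b_cols = samples[cfg.n_control + cfg.n_caseA:]
    fill_group(ctrl_cols, set())
    fill_group(a_cols, set(dysA))
    fill_group(b_cols, set(dysB))

    ds = ExpressionDataset(
        mrna=pd.DataFrame(_expr(log_m.to_numpy()), index=mrna_ids, columns=samples),
        mirna=pd.DataFrame(_expr(log_mi.to_numpy()), index=mirna_ids, columns=samples),
        lncrna=pd.DataFrame(_expr(log_l.to_numpy()), index=lnc_ids, columns=samples),
        sample_groups=group_of, value_kind="normalized",
    )

    # interaction edges.  Each triplet j owns a decoy miRNA set D_j shared by
    # its lncRNA/mRNA pair (hypergeometric signal); bridge pairs
    # (lnc_i, mrna_j) for j = i+1, i+2 reuse triplet j's miRNA and decoys so
    # the emitted network forms one component without inflating interactor
    # sets beyond the overlap.
    mm: set[tuple[str, str]] = set()
    ml: set[tuple[str, str]] = set()
    free_mirnas = mirna_ids[P:]
    decoys: list[list[str]] = []
    cursor = 0
    for j in range(P):
        d = []
        for _ in range(cfg.n_shared_extra):
            if free_mirnas:
                d.append(free_mirnas[cursor % len(free_mirnas)])
                cursor += 1
        decoys.append(d)

    for j, (l_id, mi_id, m_id) in enumerate(planted):
        for m in [mi_id] + decoys[j]:
            mm.add((m, m_id))
            ml.add((m, l_id))
    for i in range(P):
        # cyclic bridges (next and next-but-one triplet) keep the emitted
        # network one component even when a bridge triplet misses a
        # correlation cut-off at small n
        for j in ((i + 1) % P, (i + 2) % P):
            if j != i:
                for m in [planted[j][1]] + decoys[j]:
                    ml.add((m, planted[i][0]))

    n_bg_mm = int(cfg.background_edge_density * cfg.n_mirna * cfg.n_mrna)
    n_bg_ml = int(cfg.background_edge_density * cfg.n_mirna * cfg.n_lncrna)
    for _ in range(n_bg_mm):
        mm.add((mirna_ids[rng.integers(cfg.n_mirna)], mrna_ids[rng.integers(cfg.n_mrna)]))
    for _ in range(n_bg_ml):
        ml.add((mirna_ids[rng.integers(cfg.n_mirna)], lnc_ids[rng.integers(cfg.n_lncrna)]))

    truth = GroundTruth(planted, {"caseA": list(dysA), "caseB": list(dysB)})
    return ds, InteractionSet(mm, ml), truth


# -- hand-sized worked example ------------------------------------------

#: regression coefficients of the deterministic triplet in the worked example
WORKED_EXAMPLE_COEFS = {"a1": -1.0, "a2": -0.05, "c": 16.0}


def worked_example(seed: int = 7) -> tuple[ExpressionDataset, InteractionSet, GroundTruth]:
    """An 11-gene fixture small enough to check by hand.

    Two planted triplets share the miRNA ``mir-p`` (so the background network
    is a single component of five genes):

    * ``t1 = (lnc-1, mir-p, mrna-1)`` is exactly deterministic on the log2
      scale: ``mrna-1 = -1.0 * mir-p - 0.05 * mir-p * lnc-1 + 16``, with
      ``mir-p = 8 - 1.5 u`` and ``lnc-1 = 8 + 1.5 u`` for a per-sample latent
      u, so the interaction regression recovers (-1.0, -0.05, 16) with zero
      residual on control samples.
    * ``t2 = (lnc-2, mir-p, mrna-2)`` follows the same latent u with small
      independent noise (SD 0.3).

    ``t2`` is dysregulated (partners redrawn and shifted +2 log2 units) in
    caseA and caseB; ``t1`` in caseB only, where the shared miRNA is also
    shifted down by 2.

    Each planted lncRNA/mRNA pair shares four miRNAs (the planted one plus
    three decoys) out of a universe of seven, giving a shared-miRNA
    hypergeometric p of 1/35 ~ 0.029 — significant at the fixture's
    hyper_p = 0.05 (a 7-miRNA universe cannot reach p < 0.01).
    """
    rng = np.random.default_rng(seed)
    n = 8
    groups = ["control"] * n + ["caseA"] * n + ["caseB"] * n
    samples = [f"P{i:02d}" for i in range(len(groups))]

    mrna_ids = ["mrna-1", "mrna-2"]
    lnc_ids = ["lnc-1", "lnc-2"]
    mirna_ids = ["mir-p", "mir-d1", "mir-d2", "mir-d3", "mir-d4", "mir-d5", "mir-d6"]

    a1, a2, c = (WORKED_EXAMPLE_COEFS[k] for k in ("a1", "a2", "c"))

    def block(cols_n: int, dys_t1: bool, dys_t2: bool,
              shift_mir: bool) -> dict[str, np.ndarray]:
        u = rng.standard_normal(cols_n)
        mir_p = 8.0 - 1.5 * u - (2.0 if shift_mir else 0.0)
        if dys_t1:
            lnc1 = 8.0 + rng.standard_normal(cols_n) + 2.0   # broken + shifted
            mrna1 = 8.0 + rng.standard_normal(cols_n) + 2.0
        else:
            lnc1 = 8.0 + 1.5 * u
            mrna1 = a1 * mir_p + a2 * mir_p * lnc1 + c
        if dys_t2:
            lnc2 = 8.0 + rng.standard_normal(cols_n) + 2.0
            mrna2 = 8.0 + rng.standard_normal(cols_n) + 2.0
        else:
            lnc2 = 8.0 + 1.5 * u + 0.3 * rng.standard_normal(cols_n)
            mrna2 = 8.0 + 1.5 * u + 0.3 * rng.standard_normal(cols_n)
        out = {"mir-p": mir_p, "lnc-1": lnc1, "lnc-2": lnc2,
               "mrna-1": mrna1, "mrna-2": mrna2}
        for d in mirna_ids[1:]:
            out[d] = 8.0 + rng.standard_normal(cols_n)
        return out

    blocks = [block(n, False, False, False), block(n, False, True, False),
              block(n, True, True, True)]
    log = {g: np.concatenate([b[g] for b in blocks])
           for g in mrna_ids + lnc_ids + mirna_ids}

    def frame(ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame(_expr(np.vstack([log[g] for g in ids])),
                            index=ids, columns=samples)

    ds = ExpressionDataset(
        mrna=frame(mrna_ids), mirna=frame(mirna_ids), lncrna=frame(lnc_ids),
        sample_groups=pd.Series(groups, index=samples, name="group"),
        value_kind="normalized",
    )

    mm = {("mir-p", "mrna-1"), ("mir-d1", "mrna-1"), ("mir-d2", "mrna-1"),
          ("mir-d3", "mrna-1"),
          ("mir-p", "mrna-2"), ("mir-d4", "mrna-2"), ("mir-d5", "mrna-2"),
          ("mir-d6", "mrna-2")}
    ml = {("mir-p", "lnc-1"), ("mir-d1", "lnc-1"), ("mir-d2", "lnc-1"),
          ("mir-d3", "lnc-1"),
          ("mir-p", "lnc-2"), ("mir-d4", "lnc-2"), ("mir-d5", "lnc-2"),
          ("mir-d6", "lnc-2")}

    t1 = ("lnc-1", "mir-p", "mrna-1")
    t2 = ("lnc-2", "mir-p", "mrna-2")
    truth = GroundTruth([t1, t2], {"caseA": [t2], "caseB": [t1, t2]})
    return ds, InteractionSet(mm, ml), truth
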
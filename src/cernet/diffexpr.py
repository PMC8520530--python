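"""Differential expression between a case and the control group.

A deliberately simple two-sample stand-in: Welch's t-test on log2(x + 1)
values, with log2FC defined as the case-minus-control difference of
log-scale means.  Downstream scoring only consumes the pair (p, log2FC),
so tables produced by dedicated count-model tools can be imported instead
(:func:`cernet.io.read_de_table`) whenever raw-count fidelity matters.

Conventions: a gene with zero variance in both groups gets p = 1 (its fold
change is still reported); p-values are floored at the smallest positive
float because the node score takes -log10 p.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DifferentialStats, ExpressionDataset

_P_FLOOR = np.finfo(float).tiny


def welch_log_ttest(case: np.ndarray, control: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t-test rows-of-case vs rows-of-control (log scale in).

    Returns (log2FC, p).  Rows where both groups are constant get p = 1.
    """
    n1, n2 = case.shape[1], control.shape[1]
    m1, m2 = case.mean(axis=1), control.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = control.var(axis=1, ddof=1)
    fc = m1 - m2
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = np.ones_like(fc)
    ok = se2 > 0
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    return fc, np.clip(p, _P_FLOOR, 1.0)


def compute_de(ds: ExpressionDataset, case: str, control: str) -> dict[str, DifferentialStats]:
    """Per-class differential statistics for ``case`` vs ``control`` samples.

    Requires at least two samples per group.
    """
    case_samples = ds.samples_of(case)
    control_samples = ds.samples_of(control)
    for name, s in ((case, case_samples), (control, control_samples)):
        if len(s) < 2:
            raise ValueError(f"group {name!r} has {len(s)} samples; need >= 2")
    out: dict[str, DifferentialStats] = {}
    for rna_class in ("mRNA", "miRNA", "lncRNA"):
        log = ds.log2(rna_class)
        fc, p = welch_log_ttest(
            log[case_samples].to_numpy(), log[control_samples].to_numpy()
        )
        out[rna_class] = DifferentialStats(
            pd.DataFrame({"log2FC": fc, "p": p}, index=log.index), rna_class
        )
    return out


def select_sde(stats_: DifferentialStats, p_thr: float = 0.01, fc_thr: float = 1.2) -> set[str]:
    """Significantly differentially expressed genes: p < p_thr and |log2FC| > fc_thr.

    Both inequalities are strict.
    """
    if p_thr <= 0 or fc_thr <= 0:
        raise ValueError("thresholds must be positive")
    t = stats_.table
    mask = (t["p"] < p_thr) & (t["log2FC"].abs() > fc_thr)
    return set(t.index[mask])
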
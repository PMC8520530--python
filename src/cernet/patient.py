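"""Per-patient triplet dysregulation scores from a control-fitted regression.

Under the ceRNA hypothesis the mRNA of a triplet follows

    Exp_mRNA = a1 * Exp_miRNA + a2 * Exp_miRNA * Exp_lncRNA + c

in healthy samples (log2(x + 1) scale).  The coefficients are estimated by
ordinary least squares on control samples only; the per-patient
dysregulation score is the estimated-minus-observed mRNA expression,

    DS = (a1 * m + a2 * m * l + c) - y,

so an over-expressed mRNA yields a negative DS, and the mean DS over the
fitting samples is exactly zero (OLS residual property with an intercept).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, Triplet


@dataclass
class TripletRegressionResult:
    triplet: tuple[str, str, str]
    a1: float
    a2: float
    c: float
    rss: float
    n_fit: int


class TripletRegression:
    """sklearn-style estimator for the mRNA ~ miRNA + miRNA:lncRNA model.

    ``fit`` takes the log-scale member vectors over control samples;
    ``predict`` returns estimated mRNA expression; ``dysregulation_score``
    returns estimated minus observed.
    """

    def __init__(self) -> None:
        self.a1_: float | None = None
        self.a2_: float | None = None
        self.c_: float | None = None
        self.rss_: float | None = None
        self.n_fit_: int | None = None

    def fit(self, m: np.ndarray, l: np.ndarray, y: np.ndarray) -> "TripletRegression":
        m = np.asarray(m, float)
        l = np.asarray(l, float)
        y = np.asarray(y, float)
        if not (len(m) == len(l) == len(y)):
            raise ValueError("member vectors must have equal length")
        if len(y) < 4:
            raise ValueError(f"need >= 4 fitting samples, got {len(y)}")
        X = np.column_stack([m, m * l, np.ones_like(m)])
        if np.linalg.matrix_rank(X) < 3:
            raise ValueError("rank-deficient design (constant miRNA or lncRNA?)")
        coef, res, _, _ = np.linalg.lstsq(X, y, rcond=None)
        self.a1_, self.a2_, self.c_ = (float(v) for v in coef)
        fitted = X @ coef
        self.rss_ = float(((y - fitted) ** 2).sum())
        self.n_fit_ = len(y)
        return self

    def _check_fitted(self) -> None:
        if self.a1_ is None:
            raise ValueError("regression not fitted")

    def predict(self, m: np.ndarray, l: np.ndarray) -> np.ndarray:
        self._check_fitted()
        m = np.asarray(m, float)
        l = np.asarray(l, float)
        return self.a1_ * m + self.a2_ * m * l + self.c_

    def dysregulation_score(self, m, l, y) -> np.ndarray:
        """DS = estimated - observed mRNA expression."""
        y = np.asarray(y, float)
        if np.isnan(y).any() or np.isnan(np.asarray(m, float)).any():
            raise ValueError("missing expression value")
        return self.predict(m, l) - y

    def result(self, triplet: tuple[str, str, str]) -> TripletRegressionResult:
        self._check_fitted()
        return TripletRegressionResult(triplet, self.a1_, self.a2_, self.c_,
                                       self.rss_, self.n_fit_)


def _member_logs(ds: ExpressionDataset, t: Triplet, samples: list[str]):
    for cls, gene in (("miRNA", t.mirna), ("lncRNA", t.lncrna), ("mRNA", t.mrna)):
        if gene not in ds.matrix(cls).index:
            raise KeyError(f"no {cls} expression for gene {gene!r}")
    log_m = np.log2(ds.mirna.loc[t.mirna, samples].to_numpy(float) + 1.0)
    log_l = np.log2(ds.lncrna.loc[t.lncrna, samples].to_numpy(float) + 1.0)
    log_y = np.log2(ds.mrna.loc[t.mrna, samples].to_numpy(float) + 1.0)
    return log_m, log_l, log_y


def fit_triplet_regression(t: Triplet, ds: ExpressionDataset,
                           control_group: str = "control") -> TripletRegression:
    """Fit the interaction regression on control samples of ``ds``."""
    samples = ds.samples_of(control_group)
    m, l, y = _member_logs(ds, t, samples)
    return TripletRegression().fit(m, l, y)


def patient_ds_matrix(triplets: Sequence[Triplet], ds: ExpressionDataset,
                      control_group: str = "control",
                      sample_groups: Sequence[str] | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every triplet on controls and score all requested samples.

    Returns (DS matrix triplets x samples, coefficient table).  Triplets
    whose design is rank-deficient on controls are skipped (reported in the
    coefficient table would be misleading; they are simply absent).
    """
    if sample_groups is None:
        samples = ds.samples
    else:
        wanted = set(sample_groups)
        samples = [s for s in ds.samples if ds.sample_groups[s] in wanted]
    rows, coefs = [], []
    for t in triplets:
        try:
            reg = fit_triplet_regression(t, ds, control_group)
        except ValueError:
            continue
        m, l, y = _member_logs(ds, t, samples)
        ds_vals = reg.dysregulation_score(m, l, y)
        key = "|".join(t.key)
        rows.append(pd.Series(ds_vals, index=samples, name=key))
        r = reg.result(t.key)
        coefs.append({"triplet": key, "a1": r.a1, "a2": r.a2, "c": r.c,
                      "rss": r.rss, "n_fit": r.n_fit})
    if not rows:
        raise ValueError("no triplet could be fitted")
    return pd.DataFrame(rows), pd.DataFrame(coefs)
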
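"""Diagnostic biomarker panels: random-forest elimination + SVM search.

Two stages, applied to an expression feature table (genes x samples) or a
per-patient triplet-DS matrix:

1. **Random-forest elimination** — fit a random forest, rank features by
   permutation importance, discard the lowest-scoring third (at least one
   per round), repeat until at most ``max_survivors`` remain.
2. **SVM combination search** — for every combination of survivors up to
   ``max_panel`` features, evaluate a (standardised) RBF-kernel SVM by
   leave-one-out cross-validation; keep the panel with the highest accuracy,
   ties broken by fewer features, then higher AUC, then lexicographic order.

Feature standardisation uses training-fold statistics only.  AUC is computed
from pooled held-out decision values, oriented so that the training-fold AUC
is at least 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier


def _check_features(X: pd.DataFrame, y: np.ndarray) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    if counts.min() < 2:
        raise ValueError("need at least two samples per class")
    if X.shape[1] != len(y):
        raise ValueError("feature table columns must match label length")


def oob_permutation_importance(X: np.ndarray, y: np.ndarray,
                               n_trees: int = 100,
                               rng: np.random.Generator | None = None) -> np.ndarray:
    """Random-forest permutation importance on out-of-bag samples.

    Classic forest importance (mean decrease in OOB accuracy): each tree is
    fitted on a bootstrap sample; per feature, its OOB accuracy is compared
    with the accuracy after permuting that feature's OOB values; the drop is
    averaged over trees.  Computed on held-out (OOB) samples — importance on
    the training points themselves is uninformative once the forest
    interpolates, which it always does at biopsy-scale n.

    ``X`` is samples x features.
    """
    rng = rng or np.random.default_rng()
    n, f = X.shape
    imp = np.zeros(f)
    counts = np.zeros(f)
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(oob) == 0 or len(np.unique(y[boot])) < 2:
            continue
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2**31 - 1))
        ).fit(X[boot], y[boot])
        base = (tree.predict(X[oob]) == y[oob]).mean()
        Xo = X[oob]
        for j in range(f):
            perm = Xo.copy()
            perm[:, j] = perm[rng.permutation(len(oob)), j]
            imp[j] += base - (tree.predict(perm) == y[oob]).mean()
            counts[j] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, imp / np.maximum(counts, 1), 0.0)


def rf_eliminate(X: pd.DataFrame, y: np.ndarray, seed: int = 0,
                 max_survivors: int = 10, n_trees: int = 100) -> list[str]:
    """Iterative elimination of the lowest-third OOB permutation importances.

    ``X`` is features x samples.  Returns surviving feature ids in
    descending final importance (ties broken at random, seeded).  With fewer
    than three features the input order is returned unchanged.
    """
    _check_features(X, y)
    rng = np.random.default_rng(seed)
    features = list(X.index)
    if len(features) < 3:
        return features

    def ranked(feats: list[str]) -> list[str]:
        sub = X.loc[feats].T.to_numpy(float)
        imp = oob_permutation_importance(sub, y, n_trees=n_trees, rng=rng)
        jitter = rng.random(len(feats)) * 1e-12  # random tie-break
        order = np.argsort(-(imp + jitter), kind="stable")
        return [feats[i] for i in order]

    while len(features) > max_survivors:
        order = ranked(features)
        n_drop = max(1, len(features) // 3)
        features = [f for f in order[:len(order) - n_drop] ]
        features.sort(key=list(X.index).index)  # keep stable input order between rounds
    return ranked(features)


def loocv_evaluate(X: pd.DataFrame, y: np.ndarray, panel: list[str],
                   kernel: str = "rbf") -> tuple[float, float]:
    """Leave-one-out accuracy and AUC of an SVM on the given feature panel.

    Each sample is predicted by a model trained on the remaining n - 1,
    standardised with training-fold statistics only; the AUC pools the
    held-out decision values, each oriented so that larger means the second
    class on its training fold (training-fold AUC >= 0.5).
    """
    _check_features(X, y)
    missing = [f for f in panel if f not in X.index]
    if missing:
        raise KeyError(f"panel feature {missing[0]!r} not in the table")
    sub = X.loc[panel].T.to_numpy(float)
    n = len(y)
    classes = np.unique(y)
    y01 = (y == classes[1]).astype(int)
    correct = 0
    decision = np.empty(n)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        Xtr = sub[mask]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel=kernel, C=1.0, gamma="scale").fit((Xtr - mu) / sd, y01[mask])
        xi = (sub[[i]] - mu) / sd
        correct += int(clf.predict(xi)[0] == y01[i])
        d = float(clf.decision_function(xi)[0])
        # orient so larger decision values mean class 1 on the training fold
        d_tr = clf.decision_function((Xtr - mu) / sd)
        yt = y01[mask]
        decision[i] = d if d_tr[yt == 1].mean() >= d_tr[yt == 0].mean() else -d
    accuracy = correct / n
    auc = float(roc_auc_score(y01, decision))
    return accuracy, auc


@dataclass
class BiomarkerPanel:
    features: list[str]
    accuracy: float
    auc: float
    survivors: list[str] = field(default_factory=list)
    all_results: pd.DataFrame | None = None


def svm_combination_search(X: pd.DataFrame, y: np.ndarray, survivors: list[str],
                           max_panel: int = 4, kernel: str = "rbf") -> BiomarkerPanel:
    """Exhaustive LOOCV search over combinations of the surviving features."""
    if not survivors:
        raise ValueError("no surviving features")
    max_panel = min(max_panel, len(survivors))
    rows = []
    for size in range(1, max_panel + 1):
        for combo in combinations(sorted(survivors), size):
            acc, auc = loocv_evaluate(X, y, list(combo), kernel)
            rows.append({"panel": combo, "size": size, "accuracy": acc, "auc": auc})
    table = pd.DataFrame(rows)
    best = table.sort_values(
        by=["accuracy", "size", "auc", "panel"],
        ascending=[False, True, False, True], kind="stable",
    ).iloc[0]
    return BiomarkerPanel(
        features=list(best["panel"]), accuracy=float(best["accuracy"]),
        auc=float(best["auc"]), survivors=list(survivors), all_results=table,
    )


def select_biomarkers(X: pd.DataFrame, y: np.ndarray, seed: int = 0,
                      max_survivors: int = 10, max_panel: int = 4,
                      kernel: str = "rbf") -> BiomarkerPanel:
    """Full pipeline: RF elimination, then SVM combination search.

    ``X`` is features x samples (expression of one RNA class, or a
    triplet-DS matrix — the latter yields ceRNA-triplet panels).
    Constant features are removed up front.
    """
    keep = X.index[X.std(axis=1, ddof=0) > 0]
    X = X.loc[keep]
    if X.empty:
        raise ValueError("all features are constant")
    survivors = rf_eliminate(X, y, seed=seed, max_survivors=max_survivors)
    return svm_combination_search(X, y, survivors, max_panel=max_panel, kernel=kernel)
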
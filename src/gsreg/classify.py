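"""Cross-validated SVM classification of functionome profiles.

Samples are classified case vs control from their GSR-index vectors
with a radial-basis-kernel support vector machine under stratified
k-fold cross-validation (default 5 folds) repeated r times (default 10)
with per-repeat reshuffling.  Within each repeat, out-of-fold
predictions are pooled into one confusion table; sensitivity,
specificity and accuracy come from those counts, and the AUC from the
pooled decision values via the rank (Mann–Whitney) formulation with
ties counted one half.

The kernel bandwidth defaults to the median heuristic — gamma =
1 / (2 * median^2) over pairwise training distances — and the
regularisation constant to 1; both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "ConfusionCounts",
    "ClassificationReport",
    "auc_score",
    "compute_metrics",
    "median_heuristic_gamma",
    "cross_validated_svm",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random positive outscores a random negative.

    Rank-based (Mann–Whitney) formulation; ties count one half.
    ``labels`` is boolean with True marking the positive class.
    """
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(np.asarray(scores, dtype=float))
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(
    counts: ConfusionCounts,
    scores: np.ndarray,
    labels: np.ndarray,
) -> dict[str, float]:
    """Sensitivity, specificity, accuracy from counts; AUC from scores."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    return {
        "sensitivity": counts.tp / pos if pos else float("nan"),
        "specificity": counts.tn / neg if neg else float("nan"),
        "accuracy": (counts.tp + counts.tn) / counts.total,
        "auc": auc_score(scores, labels),
    }


def median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF gamma from the median pairwise Euclidean distance."""
    d = pdist(np.asarray(X, dtype=float))
    med = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
    return 1.0 / (2.0 * med * med)


@dataclass(frozen=True)
class ClassificationReport:
    """Per-repeat and aggregate cross-validation performance.

    ``per_repeat`` has one row per repeat (confusion counts and rates);
    ``scores`` one row per (sample, repeat) with the pooled decision
    value and the true label; ``aggregate`` holds the mean, min and max
    of each rate over repeats.
    """

    per_repeat: pd.DataFrame
    scores: pd.DataFrame
    aggregate: pd.DataFrame
    folds: int
    repeats: int
    seed: int


def cross_validated_svm(
    profiles: pd.DataFrame,
    labels: pd.Series,
    positive_label: str,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    C: float = 1.0,
    gamma: float | str = "median",
    fold_averaged: bool = False,
) -> ClassificationReport:
    """Repeated stratified k-fold RBF-SVM classification of profiles.

    ``profiles`` is a samples x sets GSR matrix; ``labels`` maps each
    sample to one of exactly two group labels, ``positive_label`` being
    the case class.  Metrics are pooled over folds within each repeat;
    with ``fold_averaged`` the rates are instead averaged over folds
    (AUC stays pooled, since per-fold AUC is unstable at small n).
    """
    labels = labels.loc[profiles.index]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not among {classes}")
    y = (labels == positive_label).to_numpy()
    if y.sum() < folds or (~y).sum() < folds:
        raise ValueError(f"each class needs >= {folds} samples for {folds}-fold CV")

    X = profiles.to_numpy(dtype=float)
    if gamma == "median":
        gamma_value = median_heuristic_gamma(X)
    else:
        gamma_value = float(gamma)

    repeat_rows = []
    score_rows = []
    for rep in range(repeats):
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        pred = np.empty(len(y), dtype=bool)
        decision = np.empty(len(y), dtype=float)
        fold_rates = []
        for train, test in splitter.split(X, y):
            model = SVC(kernel="rbf", C=C, gamma=gamma_value)
            model.fit(X[train], y[train])
            decision[test] = model.decision_function(X[test])
            pred[test] = model.predict(X[test])
            if fold_averaged:
                c = _confusion(y[test], pred[test])
                fold_rates.append(
                    (
                        c.tp / (c.tp + c.fn) if c.tp + c.fn else np.nan,
                        c.tn / (c.tn + c.fp) if c.tn + c.fp else np.nan,
                        (c.tp + c.tn) / c.total,
                    )
                )
        counts = _confusion(y, pred)
        metrics = compute_metrics(counts, decision, y)
        if fold_averaged:
            sens, spec, acc = np.nanmean(np.array(fold_rates), axis=0)
            metrics.update(sensitivity=sens, specificity=spec, accuracy=acc)
        repeat_rows.append(
            {
                "repeat": rep + 1,
                "tp": counts.tp,
                "fp": counts.fp,
                "tn": counts.tn,
                "fn": counts.fn,
                **metrics,
            }
        )
        for sample, score, truth in zip(profiles.index, decision, y):
            score_rows.append(
                {
                    "sample": sample,
                    "repeat": rep + 1,
                    "decision_value": score,
                    "is_case": truth,
                }
            )

    per_repeat = pd.DataFrame(repeat_rows).set_index("repeat")
    rates = per_repeat[["sensitivity", "specificity", "accuracy", "auc"]]
    aggregate = pd.DataFrame(
        {"mean": rates.mean(), "min": rates.min(), "max": rates.max()}
    )
    return ClassificationReport(
        per_repeat=per_repeat,
        scores=pd.DataFrame(score_rows),
        aggregate=aggregate,
        folds=folds,
        repeats=repeats,
        seed=seed,
    )


def _confusion(truth: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        tn=int(np.sum(~pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )
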
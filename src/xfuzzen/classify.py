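"""PD-vs-control classification from a symmetry feature.

A radial-basis-function SVM is evaluated with leave-one-out (LOO)
cross-validation: each subject is predicted by a model trained on all the
others, with feature standardisation and the kernel width estimated inside
each training fold only (no information from the held-out subject leaks into
its own prediction).  Confusion counts, sensitivity/specificity/accuracy and a
rank-based ROC area computed from the held-out decision values summarise the
performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "ClassificationReport",
    "metrics_from_counts",
    "roc_area",
    "loo_svm",
]


@dataclass(frozen=True)
class ClassificationReport:
    """Leave-one-out classification outcome.

    Percent metrics are rounded to two decimals.  ``informative`` is False
    when the feature carried no information in some training fold (zero
    variance), in which case every prediction defaulted to the negative class.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    accuracy: float
    roc_area: float
    predictions: np.ndarray      # predicted labels, subject order preserved
    scores: np.ndarray           # held-out decision values
    positive_label: object
    informative: bool = True

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "roc_area": self.roc_area,
            "positive_label": str(self.positive_label),
            "informative": self.informative,
            "predictions": [str(p) for p in self.predictions],
            "scores": [float(s) for s in self.scores],
        }


def metrics_from_counts(
    tp: int, fn: int, tn: int, fp: int
) -> tuple[float, float, float]:
    """Sensitivity, specificity and accuracy (percent, 2 decimals) from
    confusion counts: ``100*tp/(tp+fn)``, ``100*tn/(tn+fp)``,
    ``100*(tp+tn)/total``."""
    for name, c in (("tp", tp), ("fn", fn), ("tn", tn), ("fp", fp)):
        if c < 0 or int(c) != c:
            raise ValueError(f"{name} must be a nonnegative integer")
    if tp + fn < 1:
        raise ValueError("no positive subjects (tp + fn == 0)")
    if tn + fp < 1:
        raise ValueError("no negative subjects (tn + fp == 0)")
    sensitivity = round(100.0 * tp / (tp + fn), 2)
    specificity = round(100.0 * tn / (tn + fp), 2)
    accuracy = round(100.0 * (tp + tn) / (tp + fn + tn + fp), 2)
    return sensitivity, specificity, accuracy


def roc_area(
    scores: Sequence[float], labels: Sequence, positive: object
) -> float:
    """Rank-based ROC area: the probability that a random positive subject's
    score exceeds a random negative subject's, ties counted one half.

    Equivalent to the Mann-Whitney U statistic normalised by the number of
    positive-negative pairs; invariant under strictly monotone transforms of
    the scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def _median_heuristic_gamma(X: np.ndarray) -> Optional[float]:
    """RBF kernel coefficient from the median pairwise distance of the
    training features: gamma = 1 / (2 * median(d)^2).  None when the median
    distance is zero (degenerate feature)."""
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(X.shape[0], k=1)
    med = float(np.median(d[iu]))
    if med <= 0:
        return None
    return 1.0 / (2.0 * med**2)


def loo_svm(
    features: Union[Sequence[float], np.ndarray],
    labels: Sequence,
    positive: object = "PD",
    C: float = 1.0,
    gamma: Union[str, float] = "median",
    standardize: bool = True,
) -> ClassificationReport:
    """Leave-one-out RBF-SVM evaluation of a feature (scalar or vector).

    Parameters
    ----------
    features : (n,) or (n, d) array
    labels : sequence of class labels; ``positive`` names the positive class.
    C : SVM regularisation constant (default 1).
    gamma : "median" for the per-fold median-distance heuristic, or a number.
    standardize : standardise features with training-fold statistics only.

    Ties and on-margin decision values (score exactly 0) resolve to the
    negative class.  A training fold with zero feature variance yields a
    negative-class prediction and clears the ``informative`` flag.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels length mismatch")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, found {classes.tolist()}")
    if positive not in classes:
        raise ValueError(f"positive label {positive!r} not among {classes.tolist()}")
    negative = classes[classes != positive][0]
    if min((y == positive).sum(), (y == negative).sum()) < 2:
        raise ValueError("need at least 2 subjects per class")

    n = X.shape[0]
    y_bin = (y == positive).astype(int)  # sklearn orders classes [0, 1]
    scores = np.empty(n)
    informative = True
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr = X[mask], y_bin[mask]
        X_te = X[i : i + 1]
        if standardize:
            mu = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0)
            if np.any(sd == 0):
                informative = False
                scores[i] = -np.inf  # degenerate fold: default to negative
                continue
            X_tr = (X_tr - mu) / sd
            X_te = (X_te - mu) / sd
        g = _median_heuristic_gamma(X_tr) if gamma == "median" else float(gamma)
        if g is None:
            informative = False
            scores[i] = -np.inf
            continue
        clf = SVC(C=C, kernel="rbf", gamma=g)
        clf.fit(X_tr, y_tr)
        scores[i] = float(clf.decision_function(X_te)[0])

    pred_pos = scores > 0  # on-margin (0) resolves to the negative class
    predictions = np.where(pred_pos, positive, negative)
    tp = int(np.sum(pred_pos & (y_bin == 1)))
    fn = int(np.sum(~pred_pos & (y_bin == 1)))
    tn = int(np.sum(~pred_pos & (y_bin == 0)))
    fp = int(np.sum(pred_pos & (y_bin == 0)))
    sens, spec, acc = metrics_from_counts(tp, fn, tn, fp)
    finite_scores = np.where(np.isfinite(scores), scores, np.min(scores[np.isfinite(scores)]) - 1.0 if np.isfinite(scores).any() else 0.0)
    auc = roc_area(finite_scores, y, positive)
    return ClassificationReport(
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        roc_area=auc,
        predictions=predictions,
        scores=scores,
        positive_label=positive,
        informative=informative,
    )
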
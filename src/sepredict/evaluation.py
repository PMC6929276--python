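"""Classifier evaluation: confusion-matrix metrics, ROC/AUC, feature ranking.

Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 = 2PR/(P+R),
Accuracy = (TP+TN)/n. AUC uses the Mann-Whitney statistic (ties count 1/2),
which equals the trapezoidal area under the FPR-TPR curve. Features are
ranked by the absolute Pearson correlation between each column and the
binary label vector (the point-biserial correlation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero; names the metric rather than faking 0."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class EvalReport:
    """Metrics of one evaluation; undefined entries are NaN in lenient mode."""

    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float = float("nan")
    roc_points: list[tuple[float, float]] | None = None

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Two-decimal view used in human-readable reports."""
        return {k: round(getattr(self, k), ndigits)
                for k in ("precision", "recall", "f1", "accuracy", "auc")}


def confusion(labels, predictions) -> ConfusionCounts:
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape:
        raise ValueError(
            f"length mismatch: {labels.shape} labels vs {predictions.shape} predictions")
    tp = int(((labels == 1) & (predictions == 1)).sum())
    fp = int(((labels == 0) & (predictions == 1)).sum())
    tn = int(((labels == 0) & (predictions == 0)).sum())
    fn = int(((labels == 1) & (predictions == 0)).sum())
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def precision_recall_f1(counts: ConfusionCounts) -> tuple[float, float, float]:
    if counts.TP + counts.FP == 0:
        raise UndefinedMetricError("precision undefined: no predicted positives")
    if counts.TP + counts.FN == 0:
        raise UndefinedMetricError("recall undefined: no true positives in labels")
    precision = counts.TP / (counts.TP + counts.FP)
    recall = counts.TP / (counts.TP + counts.FN)
    if precision + recall == 0:
        raise UndefinedMetricError("F1 undefined: precision + recall is 0")
    f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def accuracy(counts: ConfusionCounts) -> float:
    if counts.n == 0:
        raise UndefinedMetricError("accuracy undefined on zero samples")
    return (counts.TP + counts.TN) / counts.n


def roc_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC points at every distinct threshold and the Mann-Whitney AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    # Mann-Whitney with average ranks: ties contribute 1/2
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    # curve: sweep thresholds from high to low over distinct scores
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_labels == 1)
    fps = np.cumsum(sorted_labels == 0)
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    cut = np.append(distinct, len(sorted_scores) - 1)
    points = [(0.0, 0.0)]
    points.extend((fps[i] / n_neg, tps[i] / n_pos) for i in cut)
    return points, float(auc)


def evaluate_predictions(labels, predictions, scores=None,
                         strict: bool = True) -> EvalReport:
    """Build a full report; ``strict=False`` turns undefined metrics into NaN.

    The lenient mode exists for cross-validation folds where a degenerate
    model (e.g. all-negative) makes precision undefined.
    """
    counts = confusion(labels, predictions)
    acc = accuracy(counts)
    try:
        precision, recall, f1 = precision_recall_f1(counts)
    except UndefinedMetricError:
        if strict:
            raise
        precision = recall = f1 = float("nan")
    auc = float("nan")
    roc_points = None
    if scores is not None:
        try:
            roc_points, auc = roc_auc(scores, labels)
        except ValueError:
            if strict:
                raise
    return EvalReport(counts=counts, accuracy=acc, precision=precision,
                      recall=recall, f1=f1, auc=auc, roc_points=roc_points)


def pearson_rank(feature_matrix) -> list[tuple[str, float]]:
    """Rank features by |point-biserial r| against the label vector.

    Constant columns have undefined r; they are excluded from the ranking
    (a message-worthy condition the caller can detect by length).
    """
    X = feature_matrix.values.to_numpy(dtype=float)
    y = feature_matrix.labels.astype(float)
    names = list(feature_matrix.values.columns)
    if y.std() == 0:
        raise ValueError("labels are constant; correlation undefined")
    sx = X.std(axis=0)
    usable = sx > 0
    if not usable.any():
        raise ValueError("all feature columns are constant")
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    n = len(y)
    r = np.full(X.shape[1], np.nan)
    r[usable] = (Xc[:, usable].T @ yc) / (n * sx[usable] * y.std())
    ranked = [(names[j], float(r[j])) for j in np.argsort(-np.abs(r))
              if usable[j]]
    return ranked
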
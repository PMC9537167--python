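"""Evaluation metrics for binary classifiers.

Confusion-count metrics follow the printed formulas exactly. Two "AUC"
quantities are deliberately distinct:

* ``auc_paper`` = (TPR + TNR) / 2 — a threshold-based quantity equal to
  balanced accuracy;
* ``auc_roc`` — the ranking area under the ROC curve (Mann-Whitney
  statistic, ties counted 1/2).

Undefined metrics (zero denominators, single-class inputs) are reported
as None and the metric name is listed in ``EvalReport.undefined`` rather
than silently coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("at least one count must be positive")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalReport:
    """Bundle of confusion-derived (and optionally ranking) metrics."""

    counts: ConfusionCounts | None = None
    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None  # TPR
    tnr: float | None = None
    f1: float | None = None
    mcc: float | None = None
    auc_paper: float | None = None  # (TPR + TNR) / 2
    auc_roc: float | None = None
    aupr: float | None = None
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "tnr": self.tnr,
            "f1": self.f1,
            "mcc": self.mcc,
            "auc_paper": self.auc_paper,
            "auc_roc": self.auc_roc,
            "aupr": self.aupr,
        }


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(counts: ConfusionCounts) -> EvalReport:
    """All confusion-count metrics from TP/TN/FP/FN.

    MCC requires at least one actual positive and one actual negative
    (and one predicted positive / negative); otherwise its denominator is
    zero and it is reported as undefined.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    report = EvalReport(counts=counts)

    report.accuracy = (tp + tn) / counts.n
    report.precision = _ratio(tp, tp + fp)
    report.recall = _ratio(tp, tp + fn)
    report.tnr = _ratio(tn, tn + fp)

    if report.recall is not None and report.precision is not None:
        if report.recall + report.precision > 0:
            report.f1 = (
                2 * report.recall * report.precision
                / (report.recall + report.precision)
            )
        else:
            report.f1 = 0.0

    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if mcc_den > 0:
        report.mcc = (tp * tn - fp * fn) / mcc_den

    if report.recall is not None and report.tnr is not None:
        report.auc_paper = (report.recall + report.tnr) / 2

    for name, value in report.as_dict().items():
        if name in ("auc_roc", "aupr"):
            continue
        if value is None:
            report.undefined.append(name)
    return report


def counts_from_predictions(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts from parallel 0/1 arrays (1 = positive)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def roc_auc(scores, labels) -> float | None:
    """Area under the ROC curve; ties count 1/2 (Mann-Whitney).

    Returns None (undefined) when only one class is present.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        return None
    return float(roc_auc_score(labels, scores))


def pr_curve_aupr(scores, labels) -> tuple[np.ndarray, float | None]:
    """Precision-recall points and AUPR by step-wise average precision.

    Returns (points, aupr) where points is an (n, 2) array of
    (recall, precision) pairs at every threshold, highest recall first in
    sklearn's convention reversed to ascending recall. AUPR is None when
    no positives exist.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.sum() == 0:
        return np.empty((0, 2)), None
    precision, recall, _ = precision_recall_curve(labels, scores)
    points = np.column_stack([recall[::-1], precision[::-1]])
    ap = float(average_precision_score(labels, scores))
    return points, ap


def cross_entropy_loss(pos_probs, neg_probs, eps: float = 1e-7) -> float:
    """Binary cross-entropy over positive and negative scored examples.

    Loss = -1/(m+n) [ sum_i log f(x_i+) + sum_j log(1 - f(x_j-)) ]
    with m positives scored ``pos_probs`` and n negatives ``neg_probs``
    (each prob = predicted probability of the positive class), clipped to
    [eps, 1 - eps].
    """
    pos = np.clip(np.asarray(pos_probs, dtype=float), eps, 1 - eps)
    neg = np.clip(np.asarray(neg_probs, dtype=float), eps, 1 - eps)
    m, n = pos.size, neg.size
    if m + n == 0:
        raise ValueError("empty input")
    return float(-(np.log(pos).sum() + np.log1p(-neg).sum()) / (m + n))


def evaluate_scores(
    scores, labels, threshold: float = 0.5
) -> EvalReport:
    """Full report from continuous scores: threshold for confusion
    metrics, ranking for auc_roc / aupr."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    report = confusion_metrics(
        counts_from_predictions(labels, (scores >= threshold).astype(int))
    )
    report.auc_roc = roc_auc(scores, labels)
    if report.auc_roc is None:
        report.undefined.append("auc_roc")
    _, report.aupr = pr_curve_aupr(scores, labels)
    if report.aupr is None:
        report.undefined.append("aupr")
    return report


def format_metric_row(
    target: str, algorithm: str, seed: int, split: str, report: EvalReport
) -> str:
    """One tab-separated row of a metrics table."""
    fields = [target, algorithm, str(seed), split]
    for value in report.as_dict().values():
        fields.append("NA" if value is None else f"{value:.4f}")
    return "\t".join(fields)


METRIC_TABLE_HEADER = "\t".join(
    ["target", "algorithm", "seed", "split",
     "accuracy", "precision", "recall", "tnr", "f1", "mcc",
     "auc_paper", "auc_roc", "aupr"]
)
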
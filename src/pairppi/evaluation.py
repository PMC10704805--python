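"""Threshold metrics and ranking curves for imbalanced pair classification.

With a 1:10 positive:negative design, accuracy alone is uninformative (a
reject-everything classifier scores ~0.91), so the suite reports the full
confusion-matrix family — accuracy, specificity, precision, recall and
Matthews correlation coefficient — plus the PR and ROC curves and their
areas. A random scorer's AUPR equals the positive prevalence (1/11 here),
which is the floor against which AUPR values should be read.

Metrics whose denominator is zero are reported as NaN ("undefined"),
never silently 0: on heavily imbalanced strata an all-negative predictor
has undefined precision, which is materially different from precision 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion-matrix counts at a fixed threshold."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The five scalar metrics; undefined values (zero denominator) are NaN."""

    accuracy: float
    specificity: float
    precision: float
    recall: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "precision": self.precision,
            "recall": self.recall,
            "mcc": self.mcc,
        }


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/TN/FP/FN at the >= threshold decision rule."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError(
            f"labels and scores lengths differ: {labels.shape} vs {scores.shape}"
        )
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be binary (0/1)")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Evaluate the five confusion-matrix metrics.

    accuracy    = (TP+TN) / (TP+FP+TN+FN)
    specificity = TN / (TN+FP)            (= 1 - FPR)
    precision   = TP / (TP+FP)
    recall      = TP / (TP+FN)            (= TPR)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    return MetricsReport(
        accuracy=_ratio(tp + tn, counts.total),
        specificity=_ratio(tn, tn + fp),
        precision=_ratio(tp, tp + fp),
        recall=_ratio(tp, tp + fn),
        mcc=(tp * tn - fp * fn) / mcc_den if mcc_den > 0 else math.nan,
    )


def reconstruct_confusion(
    recall: float, precision: float, n_pos: int, n_neg: int
) -> ConfusionCounts:
    """Recover integer confusion counts from printed recall/precision.

    Published tables often report only rounded recall and precision plus
    the stratum sizes; this inverts them: TP = round(recall * n_pos),
    FN = n_pos - TP, FP = round(TP * (1-precision)/precision),
    TN = n_neg - FP. Lets one cross-check a table's accuracy and MCC
    columns against its recall/precision columns.
    """
    if not (0.0 < recall <= 1.0 and 0.0 < precision <= 1.0):
        raise ValueError("recall and precision must lie in (0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("n_pos and n_neg must be positive")
    tp = round(recall * n_pos)
    fn = n_pos - tp
    fp = round(tp * (1.0 - precision) / precision)
    if fp > n_neg:
        raise ValueError(
            f"infeasible inputs: implied FP={fp} exceeds n_neg={n_neg}"
        )
    tn = n_neg - fp
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass(frozen=True)
class CurveReport:
    """PR and ROC curves with their areas."""

    pr_curve: np.ndarray  # columns: recall, precision (threshold sweep)
    roc_curve: np.ndarray  # columns: fpr, tpr
    aupr: float
    auroc: float


def pr_roc(labels, scores) -> CurveReport:
    """Sweep thresholds over the unique scores and report both curves.

    AUROC is the trapezoidal area under (FPR, TPR); AUPR uses step-wise
    (average-precision) integration, which avoids the optimistic bias of
    linear PR interpolation. Requires both classes present.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores lengths differ")
    if np.unique(labels).size < 2:
        raise ValueError("pr_roc requires both classes present")
    prec, rec, _ = precision_recall_curve(labels, scores)
    fpr, tpr, _ = roc_curve(labels, scores)
    auroc = float(np.trapezoid(tpr, fpr))
    aupr = float(average_precision_score(labels, scores))
    pr = np.column_stack([rec[::-1], prec[::-1]])
    roc = np.column_stack([fpr, tpr])
    return CurveReport(pr_curve=pr, roc_curve=roc, aupr=aupr, auroc=auroc)


def evaluate(labels, scores, threshold: float = 0.5) -> dict[str, float]:
    """One-call summary: the five threshold metrics plus AUPR and AUROC."""
    report = metrics(confusion(labels, scores, threshold)).as_dict()
    curves = pr_roc(labels, scores)
    report["aupr"] = curves.aupr
    report["auroc"] = curves.auroc
    return report
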
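"""Binary classification metrics for activity prediction.

Implements the confusion-matrix metrics (accuracy, F1, MCC, recall,
precision, specificity) directly from their defining formulas, plus the
rank-based (Mann-Whitney) ROC-AUC with half-credit for ties.  Any metric
whose denominator is zero is reported as 0 — this convention makes the
degenerate all-negative predictor yield F1 = 0 and recall = 0 rather than
an undefined value, and keeps MCC defined for one-class predictions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
from scipy.stats import rankdata


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    roc_auc: Optional[float]
    f1: float
    mcc: float
    recall: float
    precision: float
    specificity: float
    n: int

    TSV_COLUMNS = ("accuracy", "roc_auc", "f1", "mcc", "recall", "precision", "specificity")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    def to_tsv(self) -> str:
        header = "\t".join(self.TSV_COLUMNS)
        vals = "\t".join(
            "" if getattr(self, c) is None else f"{getattr(self, c):.4f}"
            for c in self.TSV_COLUMNS
        )
        return f"{header}\n{vals}\n"


def _as_binary(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if not np.all(np.isin(arr, (0, 1))):
        raise ValueError(f"{name} must contain only 0/1 entries")
    return arr.astype(np.intp)


def confusion_counts(labels, predicted) -> ConfusionCounts:
    y = _as_binary(labels, "labels")
    p = _as_binary(predicted, "predicted")
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def classification_metrics(c: ConfusionCounts) -> MetricsReport:
    """All confusion-matrix metrics; ROC-AUC is left unset (needs scores)."""
    if c.total < 1:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    f1 = _safe_div(2.0 * precision * recall, precision + recall)
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den)
    return MetricsReport(
        accuracy=(tp + tn) / c.total,
        roc_auc=None,
        f1=f1,
        mcc=mcc,
        recall=recall,
        precision=precision,
        specificity=specificity,
        n=c.total,
    )


def roc_auc(labels, scores) -> float:
    """P(score_pos > score_neg) with ties counted ½ (Mann-Whitney formulation)."""
    y = _as_binary(labels, "labels")
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC undefined: both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties with half credit
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_predictions(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Full report: threshold scores strictly at `threshold`, plus ROC-AUC."""
    s = np.asarray(scores, dtype=np.float64)
    preds = (s > threshold).astype(int)
    report = classification_metrics(confusion_counts(labels, preds))
    y = _as_binary(labels, "labels")
    if 0 < y.sum() < y.size:
        report.roc_auc = roc_auc(labels, s)
    return report
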
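"""Binary-classification evaluation parameters.

Implements the seven evaluation parameters used throughout the package,
with TF as the positive class:

* sensitivity = 100 * TP / (TP + FN)
* specificity = 100 * TN / (TN + FP)
* accuracy    = 100 * (TP + TN) / (TP + FP + TN + FN)
* F1          = 2TP / (2TP + FP + FN)
* MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
* Cohen's kappa = (p_o - p_e) / (1 - p_e), with p_o the observed accuracy
  and p_e the chance agreement from the confusion marginals
* AUC — area under the ROC curve, computed as the Mann-Whitney probability
  that a random positive outscores a random negative, ties counted half.

Conventions for degenerate inputs: any ratio with a zero denominator
(sensitivity, specificity, F1, MCC, kappa) is defined as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .seqio import TF

METRIC_COLUMNS = ["Sens", "Spec", "Acc", "AUC", "F1", "K", "MCC"]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP / FP / TN / FN with TF as the positive class."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """The seven evaluation parameters; ``auc`` is None when no scores were supplied."""

    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    kappa: float
    mcc: float
    auc: float | None = None

    def as_row(self) -> dict[str, float | None]:
        return {
            "Sens": self.sensitivity,
            "Spec": self.specificity,
            "Acc": self.accuracy,
            "AUC": self.auc,
            "F1": self.f1,
            "K": self.kappa,
            "MCC": self.mcc,
        }

    def to_tsv(self) -> str:
        """One header + one value row, in the Sens/Spec/Acc/AUC/F1/K/MCC layout."""
        row = self.as_row()
        vals = "\t".join("NA" if row[c] is None else f"{row[c]:.4f}" for c in METRIC_COLUMNS)
        return "\t".join(METRIC_COLUMNS) + "\n" + vals + "\n"


def _as_binary(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return (arr == TF).astype(int)
    return arr.astype(int)


def confusion_counts(y_true: Sequence, y_pred: Sequence) -> ConfusionCounts:
    """Count TP/FP/TN/FN. Labels may be TF/nonTF strings or 0/1 integers."""
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    if len(y_true) == 0:
        raise ValueError("cannot build a confusion matrix from zero pairs")
    t = _as_binary(y_true)
    p = _as_binary(y_pred)
    return ConfusionCounts(
        TP=int(np.sum((t == 1) & (p == 1))),
        FP=int(np.sum((t == 0) & (p == 1))),
        TN=int(np.sum((t == 0) & (p == 0))),
        FN=int(np.sum((t == 1) & (p == 0))),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def threshold_metrics(c: ConfusionCounts) -> MetricsReport:
    """Threshold-dependent parameters from a confusion matrix (no AUC)."""
    n = c.total
    if n == 0:
        raise ValueError("all confusion counts are zero")
    sens = 100.0 * _safe_div(c.TP, c.TP + c.FN)
    spec = 100.0 * _safe_div(c.TN, c.TN + c.FP)
    acc = 100.0 * (c.TP + c.TN) / n
    f1 = _safe_div(2 * c.TP, 2 * c.TP + c.FP + c.FN)

    mcc_den = math.sqrt(
        float(c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    mcc = _safe_div(float(c.TP) * c.TN - float(c.FP) * c.FN, mcc_den)

    p_o = (c.TP + c.TN) / n
    p_e = (float(c.TP + c.FP) * (c.TP + c.FN) + float(c.FN + c.TN) * (c.FP + c.TN)) / (n * n)
    kappa = _safe_div(p_o - p_e, 1.0 - p_e)

    return MetricsReport(
        sensitivity=sens, specificity=spec, accuracy=acc, f1=f1, kappa=kappa, mcc=mcc
    )


def roc_auc(y_true: Sequence, scores: Sequence[float]) -> float:
    """Area under the ROC curve via the midrank Mann-Whitney statistic.

    Equivalent to trapezoidal integration of the ROC curve with tied scores
    handled by half-credit.
    """
    t = _as_binary(y_true)
    s = np.asarray(scores, dtype=float)
    if len(t) != len(s):
        raise ValueError("labels and scores differ in length")
    n_pos = int(t.sum())
    n_neg = len(t) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present in y_true")
    ranks = rankdata(s)  # midranks for ties
    return float((ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate(
    y_true: Sequence, y_pred: Sequence, scores: Sequence[float] | None = None
) -> MetricsReport:
    """Full report from labels, predictions and (optionally) scores."""
    report = threshold_metrics(confusion_counts(y_true, y_pred))
    if scores is None:
        return report
    return MetricsReport(
        sensitivity=report.sensitivity,
        specificity=report.specificity,
        accuracy=report.accuracy,
        f1=report.f1,
        kappa=report.kappa,
        mcc=report.mcc,
        auc=roc_auc(y_true, scores),
    )
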
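"""Evaluation metrics: RMSE / R² for regression, and the standard
confusion-matrix statistics (accuracy, precision, recall, F1, MCC) for
binary classification.

These are implemented directly from their defining formulas rather than
delegated, because they are part of this package's evaluation contract
and are cross-checked in the test suite against independent brute-force
recomputation.

Zero-denominator conventions: precision, recall and F1 return 0.0 with a
``degenerate`` flag when their denominator vanishes; MCC likewise
returns 0.0 with the flag when any marginal of the confusion matrix is
empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class EvalPairs:
    """Observed / predicted value pairs for a regression evaluation."""

    obs: np.ndarray
    pred: np.ndarray

    @classmethod
    def from_sequences(cls, obs: Sequence[float], pred: Sequence[float]) -> "EvalPairs":
        o = np.asarray(obs, dtype=float)
        p = np.asarray(pred, dtype=float)
        if o.shape != p.shape or o.ndim != 1:
            raise MetricError(
                f"observed and predicted must be 1-D and equal length, got {o.shape} vs {p.shape}"
            )
        return cls(obs=o, pred=p)

    @property
    def n(self) -> int:
        return int(self.obs.size)


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        counts = (self.TP, self.TN, self.FP, self.FN)
        if any(c < 0 for c in counts):
            raise MetricError("confusion-matrix counts must be non-negative")
        if sum(counts) < 1:
            raise MetricError("confusion matrix must contain at least one record")

    @classmethod
    def from_labels(cls, obs: Sequence[int], pred: Sequence[int]) -> "ConfusionMatrix":
        o = np.asarray(obs, dtype=int)
        p = np.asarray(pred, dtype=int)
        if o.shape != p.shape:
            raise MetricError("observed and predicted labels must have equal length")
        return cls(
            TP=int(np.sum((o == 1) & (p == 1))),
            TN=int(np.sum((o == 0) & (p == 0))),
            FP=int(np.sum((o == 0) & (p == 1))),
            FN=int(np.sum((o == 1) & (p == 0))),
        )

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class CVMetrics:
    """Cross-validation and external-test metrics for one trained model.

    Regression models fill the rmse/r² fields; classification models the
    accuracy/precision/recall/F1/MCC fields.  ``per_fold`` keeps the
    fold-wise values behind each pooled cross-validation number so the
    dispersion across folds remains inspectable.
    """

    task: str = "regression"
    rmse_cv: Optional[float] = None
    r2_cv: Optional[float] = None
    rmse_test: Optional[float] = None
    r2_test: Optional[float] = None
    accuracy: Optional[float] = None
    precision: Optional[float] = None
    recall: Optional[float] = None
    f1: Optional[float] = None
    mcc: Optional[float] = None
    accuracy_test: Optional[float] = None
    precision_test: Optional[float] = None
    recall_test: Optional[float] = None
    f1_test: Optional[float] = None
    mcc_test: Optional[float] = None
    degenerate: bool = False
    per_fold: Dict[str, List[float]] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, Optional[float]]:
        keys = (
            ("rmse_cv", "r2_cv", "rmse_test", "r2_test")
            if self.task == "regression"
            else (
                "accuracy", "precision", "recall", "f1", "mcc",
                "accuracy_test", "precision_test", "recall_test", "f1_test", "mcc_test",
            )
        )
        return {k: getattr(self, k) for k in keys}


def rmse(pairs: EvalPairs) -> float:
    """Root-mean-square error, sqrt(mean((obs - pred)^2))."""
    if pairs.n < 1:
        raise MetricError("RMSE needs at least one pair")
    return float(np.sqrt(np.mean((pairs.obs - pairs.pred) ** 2)))


def r_squared(pairs: EvalPairs) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    Can be negative for predictions worse than the observed mean.
    Undefined (raises) when all observed values coincide.
    """
    if pairs.n < 2:
        raise MetricError("R² needs at least two pairs")
    ss_tot = float(np.sum((pairs.obs - pairs.obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise MetricError("R² is undefined when all observed values are equal")
    ss_res = float(np.sum((pairs.obs - pairs.pred) ** 2))
    return 1.0 - ss_res / ss_tot


def classification_metrics(cm: ConfusionMatrix) -> CVMetrics:
    """Accuracy, precision, recall, F1 and MCC from a confusion matrix."""
    tp, tn, fp, fn = (float(cm.TP), float(cm.TN), float(cm.FP), float(cm.FN))
    degenerate = False

    accuracy = (tp + tn) / cm.total

    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, degenerate = 0.0, True
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, degenerate = 0.0, True
    if precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1, degenerate = 0.0, True

    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom > 0:
        mcc = (tp * tn - fp * fn) / denom
    else:
        mcc, degenerate = 0.0, True

    return CVMetrics(
        task="classification",
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        mcc=mcc,
        degenerate=degenerate,
    )
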
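"""Imbalance-aware evaluation: sensitivity, specificity, G-mean, AUC, AUPRC.

The minority class is the positive class throughout, so sensitivity is
minority recall. The headline metric is the geometric mean of sensitivity
and specificity — an all-majority classifier scores 0 no matter how extreme
the imbalance. Ranking metrics are computed by scikit-learn:
``roc_auc`` via ``roc_auc_score`` (rank/Mann-Whitney equivalent under ties)
and ``pr_auc`` via ``average_precision_score``, whose step-wise
interpolation avoids the optimistic bias linear PR interpolation has at
extreme imbalance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .datamodel import MAJORITY, MINORITY


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts with minority = positive."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n_min(self) -> int:
        return self.tp + self.fn

    @property
    def n_maj(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_min if self.n_min else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / self.n_maj if self.n_maj else float("nan")


def confusion_counts(predicted: np.ndarray, true: np.ndarray) -> ConfusionCounts:
    """Tally the 2x2 table of predicted vs true labels (1 = minority)."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape} predictions vs {true.shape} labels"
        )
    return ConfusionCounts(
        tp=int(np.sum((predicted == MINORITY) & (true == MINORITY))),
        fn=int(np.sum((predicted == MAJORITY) & (true == MINORITY))),
        tn=int(np.sum((predicted == MAJORITY) & (true == MAJORITY))),
        fp=int(np.sum((predicted == MINORITY) & (true == MAJORITY))),
    )


def g_mean(sensitivity: float, specificity: float) -> float:
    """sqrt(sensitivity x specificity)."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return math.sqrt(sensitivity * specificity)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC area with the minority class positive; needs both classes."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(labels == MINORITY, np.asarray(scores, float)))


def pr_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Step-interpolated precision-recall area, minority positive."""
    labels = np.asarray(labels)
    if not np.any(labels == MINORITY):
        raise ValueError("pr_auc needs at least one minority example")
    return float(
        average_precision_score(labels == MINORITY, np.asarray(scores, float))
    )


@dataclass(frozen=True)
class MetricsReport:
    """One evaluation's metric set plus the per-class counts behind it."""

    sensitivity: float
    specificity: float
    g_mean: float
    auc: float
    auprc: float
    n_min: int
    n_maj: int

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "g_mean": self.g_mean,
            "auc": self.auc,
            "auprc": self.auprc,
            "n_min": self.n_min,
            "n_maj": self.n_maj,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    def to_text(self) -> str:
        rows = [
            ("Sensitivity", self.sensitivity),
            ("Specificity", self.specificity),
            ("G-mean", self.g_mean),
            ("AUC", self.auc),
            ("AUPRC", self.auprc),
        ]
        return "\n".join(f"{name:<12} {value:.3f}" for name, value in rows)


def evaluate(
    true_labels: np.ndarray, predicted: np.ndarray, scores: np.ndarray
) -> MetricsReport:
    """Bundle all metrics for one set of predictions and margin scores."""
    counts = confusion_counts(predicted, true_labels)
    return MetricsReport(
        sensitivity=counts.sensitivity,
        specificity=counts.specificity,
        g_mean=g_mean(counts.sensitivity, counts.specificity),
        auc=roc_auc(scores, true_labels),
        auprc=pr_auc(scores, true_labels),
        n_min=counts.n_min,
        n_maj=counts.n_maj,
    )
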
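"""Classification and screen-power metrics.

ROC-AUC (Mann-Whitney statistic, ties counted one half), PRC-AUC (area
under the step precision-recall curve, i.e. average precision), the
low-false-positive ROC segment, and enrichment factors at a library
fraction. ROC/PR computations delegate to scikit-learn; the enrichment
factor uses a stable descending sort so score ties resolve in input
order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve


class MetricError(ValueError):
    """Raised when a metric is undefined for the given inputs."""


@dataclass
class RankedPredictions:
    labels: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.labels.shape != self.scores.shape or self.labels.ndim != 1:
            raise ValueError("labels and scores must be equal-length 1-D arrays")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    @property
    def n(self) -> int:
        return int(self.labels.size)

    @property
    def n_active(self) -> int:
        return int(self.labels.sum())

    def _require_both_classes(self):
        if self.n_active == 0 or self.n_active == self.n:
            raise MetricError("metric undefined: only one class present")


def roc_auc(preds: RankedPredictions) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    preds._require_both_classes()
    return float(roc_auc_score(preds.labels, preds.scores))


def pr_auc(preds: RankedPredictions) -> float:
    """Area under the step precision-recall curve (average precision)."""
    preds._require_both_classes()
    return float(average_precision_score(preds.labels, preds.scores))


def roc_segment(preds: RankedPredictions, fpr_max: float) -> np.ndarray:
    """ROC points (fpr, tpr) restricted to FPR <= fpr_max, threshold-sorted."""
    if not 0 < fpr_max <= 1:
        raise ValueError(f"fpr_max must lie in (0, 1], got {fpr_max}")
    preds._require_both_classes()
    fpr, tpr, _ = roc_curve(preds.labels, preds.scores, drop_intermediate=False)
    keep = fpr <= fpr_max + 1e-12
    return np.column_stack([fpr[keep], tpr[keep]])


def enrichment_factor(preds: RankedPredictions, fraction: float) -> float:
    """EF = (actives in the top ceil(fraction*n) / k) / (n_active / n).

    Selection size k = ceil(fraction * n); ties in score resolve by input
    order (stable sort), so the result is deterministic.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    preds._require_both_classes()
    n = preds.n
    k = math.ceil(fraction * n)
    order = np.argsort(-preds.scores, kind="stable")
    top = order[:k]
    hit_rate = preds.labels[top].sum() / k
    base_rate = preds.n_active / n
    return float(hit_rate / base_rate)


def evaluate(labels, scores, ef_fractions=(0.005, 0.01, 0.05)) -> dict:
    """JSON-friendly report: AUC, PRC-AUC, and EF at the given fractions."""
    preds = RankedPredictions(labels, scores)
    report = {
        "n": preds.n,
        "n_active": preds.n_active,
        "roc_auc": roc_auc(preds),
        "pr_auc": pr_auc(preds),
    }
    for f in ef_fractions:
        report[f"ef_{f * 100:g}pct"] = enrichment_factor(preds, f)
    return report
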
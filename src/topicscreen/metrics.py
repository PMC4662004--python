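"""Screening evaluation: threshold metrics, ranking areas and the Friedman test.

Precision, recall, F1 and accuracy follow the zero-division convention used
throughout the screening literature (no predicted positives -> P = R = F1 =
0, never NaN), which is what an all-negative degenerate classifier reports
on an imbalanced corpus.  Ranking quality uses ROC-AUC (equivalently the
probability that a random relevant document outscores a random irrelevant
one, ties counting half) and PRC-AUC as step-wise average precision.

Representations and kernels are compared across corpora with the Friedman
test: metrics are ranked within each corpus (higher metric -> higher rank,
ties receive midranks), mean ranks per group are reported, and the
tie-corrected chi-square statistic with k-1 degrees of freedom gives an
asymptotic p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.stats import chi2, rankdata
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import UndefinedMetricError, ValidationError


@dataclass
class MetricSet:
    """The six screening metrics for one classifier run."""

    precision: float
    recall: float
    f1: float
    accuracy: float
    roc_auc: float = float("nan")
    prc_auc: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; zero when both are zero."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def confusion_metrics(y_true, y_pred) -> MetricSet:
    """Precision/recall/F1/accuracy from binary labels (+1 = relevant)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred lengths differ")
    if y_true.size == 0:
        raise ValidationError("empty label vectors")
    pos_t = y_true > 0
    pos_p = y_pred > 0
    tp = int(np.sum(pos_t & pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return MetricSet(
        precision=precision,
        recall=recall,
        f1=f1_from_pr(precision, recall),
        accuracy=(tp + tn) / y_true.size,
    )


def roc_auc(scores, y_true) -> float:
    """Area under the ROC curve (rank formulation: P(score+ > score-) + tie/2)."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true > 0)) < 2:
        raise UndefinedMetricError("ROC-AUC needs both classes in y_true")
    return float(roc_auc_score(y_true > 0, scores))


def prc_auc(scores, y_true) -> float:
    """Area under the precision-recall curve as step-wise average precision."""
    y_true = np.asarray(y_true)
    if not np.any(y_true > 0):
        raise UndefinedMetricError("PRC-AUC needs at least one positive")
    return float(average_precision_score(y_true > 0, scores))


def evaluate_scores(y_true, scores, threshold: float = 0.0) -> MetricSet:
    """Full metric set from real-valued margins thresholded at zero."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    y_pred = np.where(scores > threshold, 1, -1)
    ms = confusion_metrics(y_true, y_pred)
    try:
        ms.roc_auc = roc_auc(scores, y_true)
        ms.prc_auc = prc_auc(scores, y_true)
    except UndefinedMetricError:
        pass
    return ms


@dataclass
class FriedmanResult:
    """Mean ranks plus the chi-square summary of a Friedman comparison."""

    mean_ranks: np.ndarray
    statistic: float
    df: int
    p_value: float
    group_names: list[str] | None = None


def friedman_test(values, direction: str = "higher_better",
                  group_names: list[str] | None = None) -> FriedmanResult:
    """Friedman rank test over an n-datasets x k-groups table.

    Within each dataset the k group values are ranked (best value -> rank k
    under ``higher_better``; ties get midranks).  The statistic is

        chi2_F = 12 n / (k (k+1)) * sum_j (Rbar_j - (k+1)/2)^2

    divided by the standard tie-correction factor, with k-1 degrees of
    freedom.
    """
    table = np.asarray(values, dtype=float)
    if table.ndim != 2:
        raise ValidationError("values must be a 2-D table")
    n, k = table.shape
    if n < 2 or k < 3:
        raise ValidationError("need >= 2 datasets and >= 3 groups")
    if not np.all(np.isfinite(table)):
        raise ValidationError("missing or non-finite cell in the table")
    if direction not in ("higher_better", "lower_better"):
        raise ValidationError(f"unknown direction {direction!r}")
    signed = table if direction == "higher_better" else -table
    ranks = np.vstack([rankdata(row) for row in signed])
    mean_ranks = ranks.mean(axis=0)
    stat = 12.0 * n / (k * (k + 1)) * np.sum((mean_ranks - (k + 1) / 2.0) ** 2)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_sum = 0.0
    for row in signed:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_sum / (n * k * (k * k - 1))
    if correction > 0:
        stat = stat / correction
    df = k - 1
    return FriedmanResult(
        mean_ranks=mean_ranks,
        statistic=float(stat),
        df=df,
        p_value=float(chi2.sf(stat, df)),
        group_names=group_names,
    )
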
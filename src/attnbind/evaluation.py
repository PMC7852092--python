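"""Binding-prediction benchmark metrics: auROC, auPRC, recall at fixed
FDR, and the rank-based unified score.

Predictions are per-bin scores in [0,1] against binary bound/unbound
labels (ambiguous bins are excluded before scoring).  The unified score
combines a method's rank r on each of the four measures as sum(ln(r/6));
smaller is better.  The per-measure fraction r/6 is also provided
(``rank_fraction``), since published per-target summaries are commonly on
that scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score


@dataclass
class ScoredLabels:
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")


def auroc(sl: ScoredLabels) -> float:
    """Area under the ROC curve (equals the Mann-Whitney probability that
    a random positive outscores a random negative, ties counted 1/2)."""
    if len(np.unique(sl.labels)) < 2:
        raise ValueError("auROC undefined: both classes must be present")
    return float(roc_auc_score(sl.labels, sl.scores))


def auprc(sl: ScoredLabels) -> float:
    """Area under the precision-recall curve by the step-wise
    (interpolation-free) sum over descending thresholds."""
    if sl.labels.sum() == 0:
        raise ValueError("auPRC undefined: no positives")
    return float(average_precision_score(sl.labels, sl.scores))


def recall_at_fdr(sl: ScoredLabels, fdr: float) -> float:
    """Maximum recall over thresholds whose precision is >= 1 - fdr;
    0 when no threshold qualifies."""
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    precision, recall, _ = precision_recall_curve(sl.labels, sl.scores)
    ok = precision >= 1.0 - fdr
    return float(recall[ok].max()) if ok.any() else 0.0


def unified_score(ranks: Sequence[float]) -> float:
    """sum(ln(r/6)) over the four per-measure ranks; smaller is better."""
    ranks = np.asarray(ranks, dtype=np.float64)
    if ranks.shape != (4,):
        raise ValueError("expected four per-measure ranks")
    if np.any(ranks < 1):
        raise ValueError("ranks start at 1")
    return float(np.sum(np.log(ranks / 6.0)))


def rank_fraction(ranks: Sequence[float]) -> float:
    """Mean of r/6 across the four measures (the per-target convention
    used in published leaderboard summaries)."""
    ranks = np.asarray(ranks, dtype=np.float64)
    if np.any(ranks < 1):
        raise ValueError("ranks start at 1")
    return float(np.mean(ranks / 6.0))


def rank_methods(metric_values: dict[str, Sequence[float]]) -> dict[str, np.ndarray]:
    """Rank methods per measure (1 = best, higher metric = better);
    ties receive average ranks."""
    names = list(metric_values)
    table = np.asarray([metric_values[n] for n in names], dtype=np.float64)
    ranks = np.zeros_like(table)
    for j in range(table.shape[1]):
        ranks[:, j] = rankdata(-table[:, j], method="average")
    return {n: ranks[i] for i, n in enumerate(names)}


def evaluate_all(sl: ScoredLabels) -> dict[str, float]:
    return {
        "auroc": auroc(sl),
        "auprc": auprc(sl),
        "recall_at_50_fdr": recall_at_fdr(sl, 0.50),
        "recall_at_10_fdr": recall_at_fdr(sl, 0.10),
    }
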
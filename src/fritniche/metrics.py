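"""Presence/absence evaluation metrics: rank AUC, TSS, Cohen's kappa.

AUC is the Mann-Whitney rank statistic (probability a random presence
outscores a random absence, ties counting one half). TSS and kappa are
computed from the confusion matrix at a score threshold; the conventional
bands call AUC >= 0.9 and TSS > 0.75 excellent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


def _check_classes(labels: np.ndarray) -> None:
    if not (np.any(labels == 1) and np.any(labels == 0)):
        raise ValueError("both classes (0 and 1) must be present")


def auc_score(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with ties contributing 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_classes(labels)
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    tss: float
    kappa: float
    threshold: float


def confusion_metrics(scores, labels, threshold: float) -> ConfusionMetrics:
    """Sensitivity, specificity, TSS = sens + spec - 1 and kappa at a
    threshold (prediction positive iff score >= threshold)."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_classes(labels)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    n = tp + tn + fp + fn
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = 0.0 if np.isclose(p_e, 1.0) else (p_o - p_e) / (1 - p_e)
    return ConfusionMetrics(sens, spec, sens + spec - 1, kappa, threshold)


def best_tss_threshold(scores, labels) -> float:
    """Lowest threshold on the grid 0.00, 0.01, ..., 1.00 maximizing TSS."""
    grid = np.round(np.linspace(0.0, 1.0, 101), 2)
    best_t, best_tss = grid[0], -np.inf
    for t in grid:
        tss = confusion_metrics(scores, labels, t).tss
        if tss > best_tss + 1e-12:
            best_t, best_tss = t, tss
    return float(best_t)
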
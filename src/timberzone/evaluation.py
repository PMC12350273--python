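"""Discrimination and confusion-matrix metrics for suitability models.

AUC is the rank-based (Mann-Whitney) statistic with half credit for ties;
TSS = sensitivity + specificity - 1 and omission = 1 - sensitivity are
computed from exact integer counts at a closed lower threshold
("predicted present iff score >= threshold").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold


class SingleClassError(ValueError):
    """Metric undefined because only one class is present."""


def _check_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise SingleClassError("both classes required; got a single label value")


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_presence > score_absence) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_classes(labels)
    ranks = rankdata(scores)
    n1 = int((labels == 1).sum())
    n0 = labels.size - n1
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass(frozen=True)
class EvalMetrics:
    """Threshold-dependent confusion metrics plus the threshold used."""

    auc: float
    sensitivity: float
    specificity: float
    tss: float
    omission_rate: float
    accuracy: float
    threshold: float
    fold: int | None = None


def confusion_metrics(scores, labels, threshold: float) -> EvalMetrics:
    """Confusion-matrix metrics at a closed lower threshold.

    Predicted positive iff score >= threshold; counts are exact integers.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_classes(labels)
    pred = scores >= threshold
    pos = labels == 1
    tp = int((pred & pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    fp = int((pred & ~pos).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return EvalMetrics(
        auc=auc(scores, labels),
        sensitivity=sens,
        specificity=spec,
        tss=sens + spec - 1.0,
        omission_rate=1.0 - sens,
        accuracy=(tp + tn) / labels.size,
        threshold=float(threshold),
    )


def max_tss_threshold(scores, labels) -> tuple[float, float]:
    """Exhaustive scan over unique score values for the TSS-maximising cut.

    Returns ``(threshold, tss)``; the lowest threshold achieving the maximum
    wins, making the choice deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_classes(labels)
    best_t, best_tss = 0.0, -np.inf
    for t in np.unique(scores):
        m = confusion_metrics(scores, labels, float(np.clip(t, 0.0, 1.0)))
        if m.tss > best_tss + 1e-15:
            best_t, best_tss = m.threshold, m.tss
    return best_t, best_tss


def kfold_cv(features, labels, fit_eval, k: int = 10, seed: int = 0):
    """Stratified k-fold cross-validation harness.

    ``fit_eval(train_idx, test_idx) -> EvalMetrics`` does the model-specific
    work; folds are disjoint, covering, and stratified by label.  Returns
    ``(per_fold_metrics, summary)`` where summary maps each metric to its
    (mean, sd) over folds.
    """
    labels = np.asarray(labels)
    _check_classes(labels)
    minority = min(int((labels == 1).sum()), int((labels == 0).sum()))
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > minority:
        raise ValueError(
            f"k = {k} exceeds the minority class count ({minority})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    n = len(labels)
    fold_metrics: list[EvalMetrics] = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros((n, 1)), labels)):
        m = fit_eval(tr, te)
        fold_metrics.append(EvalMetrics(**{**m.__dict__, "fold": fold}))
    summary = {}
    for name in ("auc", "tss", "omission_rate", "accuracy"):
        vals = np.array([getattr(m, name) for m in fold_metrics])
        summary[name] = (float(vals.mean()), float(vals.std(ddof=1)))
    return fold_metrics, summary
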
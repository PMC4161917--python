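"""Retrieval evaluation: precision/recall, PR curves with AUC, cross-
validated ROC of the feedback classifier, and recall curves before/after
feedback.

Precision is the fraction of retrieved items that are relevant; recall is
the fraction of all relevant items that were retrieved.  Curves sweep the
retrieved-count cutoff over the ranked list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .feedback import FeedbackSet, SingleClassError, train_feedback

logger = logging.getLogger(__name__)


@dataclass
class RetrievalEvaluation:
    """Precision/recall summary of one ranked retrieval list."""

    precision: float
    recall: float
    pr_curve: np.ndarray        # (n, 2) columns: recall, precision
    auc: float
    n_relevant_total: int
    roc: np.ndarray | None = None   # (n, 2) columns: fpr, tpr


def precision_recall(
    relevance: np.ndarray, n_relevant_total: int, cutoff: int
) -> tuple[float, float]:
    """Precision and recall of the top-``cutoff`` entries.

    ``relevance`` is the ranked list's boolean relevance labels (rank
    order).  Precision = relevant-in-top-cutoff / cutoff; recall =
    relevant-in-top-cutoff / ``n_relevant_total``.
    """
    rel = np.asarray(relevance, dtype=bool)
    if cutoff < 1 or cutoff > rel.size:
        raise ValueError(f"cutoff must be in [1, {rel.size}], got {cutoff}")
    n_in_list = int(rel.sum())
    if n_relevant_total < n_in_list:
        raise ValueError(
            f"n_relevant_total={n_relevant_total} below relevant items in list ({n_in_list})"
        )
    hits = int(rel[:cutoff].sum())
    precision = hits / cutoff
    if n_relevant_total == 0:
        logger.warning("no relevant items exist; recall reported as 0")
        return precision, 0.0
    return precision, hits / n_relevant_total


def pr_curve_auc(relevance: np.ndarray, n_relevant_total: int) -> RetrievalEvaluation:
    """Precision-recall curve over all cutoffs, with trapezoidal AUC.

    The cutoff sweeps 1..len(list); recall is nondecreasing along the
    sweep, and the area is integrated over the recall axis (normalized
    [0,1] x [0,1] axes).
    """
    rel = np.asarray(relevance, dtype=bool)
    if rel.size == 0:
        raise ValueError("empty retrieval list")
    cum = np.cumsum(rel)
    cutoffs = np.arange(1, rel.size + 1)
    precisions = cum / cutoffs
    recalls = cum / n_relevant_total if n_relevant_total > 0 else np.zeros_like(precisions)
    # anchor the sweep at recall 0 with the precision of the first cutoff
    curve = np.column_stack(
        [np.concatenate([[0.0], recalls]), np.concatenate([[precisions[0]], precisions])]
    )
    auc = float(np.trapezoid(curve[:, 1], curve[:, 0]))
    p, r = precision_recall(rel, n_relevant_total, rel.size)
    return RetrievalEvaluation(
        precision=p, recall=r, pr_curve=curve, auc=auc,
        n_relevant_total=n_relevant_total,
    )


def roc_cv(
    items: FeedbackSet, folds: int = 10, seed: int = 0,
    variance_target: float = 0.90, T: int = 50,
) -> tuple[np.ndarray, float]:
    """Cross-validated ROC of the relevance-feedback classifier.

    Stratified k-fold (default 10): per fold the feedback model (PCA +
    appearance-weighted AdaBoost) is trained on the training fold and the
    held-out items are scored by ensemble margin; scores are pooled across
    folds and a single ROC curve is traced by threshold sweep.  Returns
    ``(roc, auc)`` where ``roc`` has columns (fpr, tpr).  If a class has
    fewer members than ``folds``, the fold count is reduced with a warning.
    """
    y = items.labels
    n_min = int(min(y.sum(), (~y).sum()))
    if n_min < 1:
        raise SingleClassError("ROC needs both classes present")
    if n_min < folds:
        logger.warning("smallest class has %d members; reducing folds from %d", n_min, folds)
        folds = max(2, n_min)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(len(items))
    X_idx = np.arange(len(items))
    for train_idx, test_idx in skf.split(X_idx, y):
        model = train_feedback(items.subset(train_idx), variance_target, T)
        scores[test_idx] = model.score_features(items.features[test_idx])
    fpr, tpr, _ = _sk_roc_curve(y.astype(int), scores)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def _recall_curve(relevance: np.ndarray) -> np.ndarray:
    """Recall-vs-rank curve on normalized axes for one ranked list."""
    rel = np.asarray(relevance, dtype=bool)
    total = rel.sum()
    recall = np.cumsum(rel) / total if total else np.zeros(rel.size)
    x = np.arange(1, rel.size + 1) / rel.size
    return np.column_stack([x, recall])


def _curve_area(curve: np.ndarray) -> float:
    x, y = curve[:, 0], curve[:, 1]
    return float(np.trapezoid(y, x))


def recall_after_feedback(
    items: FeedbackSet, n_train: int, seed: int = 0,
    variance_target: float = 0.90, T: int = 50,
) -> dict:
    """Recall curves of the held-out items before and after feedback.

    ``n_train`` labeled items are drawn at random (seeded; redrawn up to 50
    times if a single class is sampled), a feedback model is trained on
    them, and the remaining items are ranked by initial distance (before)
    and by ensemble margin (after).  Returns a dict with both normalized
    recall-vs-rank curves and their trapezoidal areas.
    """
    K = len(items)
    if not 0 < n_train < K:
        raise ValueError(f"n_train must be in (0, {K}), got {n_train}")
    rng = np.random.default_rng(seed)
    idx = np.arange(K)
    for _ in range(50):
        train_idx = np.sort(rng.choice(idx, size=n_train, replace=False))
        if len(np.unique(items.labels[train_idx])) == 2:
            break
    else:
        raise SingleClassError("could not draw a training sample with both classes")
    test_idx = np.setdiff1d(idx, train_idx)
    test = items.subset(test_idx)
    if not test.labels.any():
        logger.warning("all relevant items fell in the training sample; "
                       "held-out recall curve is degenerate")

    model = train_feedback(items.subset(train_idx), variance_target, T)
    before_order = np.argsort(test.distances, kind="stable")
    scores = model.score_features(test.features)
    after_order = sorted(range(len(test)), key=lambda k: (-scores[k], k))

    before = _recall_curve(test.labels[before_order])
    after = _recall_curve(test.labels[np.asarray(after_order)])
    return {
        "before_curve": before,
        "after_curve": after,
        "area_before": _curve_area(before),
        "area_after": _curve_area(after),
        "train_idx": train_idx,
    }
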
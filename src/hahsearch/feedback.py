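"""Dual-similarity relevance feedback.

After the initial retrieval, a reviewer labels the top-ranked patches (by
default the first 100) as relevant or non-relevant.  Re-ranking then
combines two similarities: semantic similarity from the labels, and visual
appearance similarity from the feature distances to the query.  The
appearance side enters through the *initial sample distribution* of an
AdaBoost ensemble: instead of uniform weights, training starts from weights
that decrease with the item's distance to the query, so visually similar
examples dominate the first boosting rounds.

Pipeline: the coarse annular-histogram features (dimension ``256*3*r``) of
the feedback set are reduced by PCA to the smallest number of components
capturing 90% of the variance, a discrete AdaBoost ensemble of decision
stumps is trained from the appearance-weighted distribution, and items are
re-ordered by descending ensemble margin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.tree import DecisionTreeClassifier

from .geometry import PatchWindow
from .search import RankedCandidates

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 100
DEFAULT_ROUNDS = 50
DEFAULT_VARIANCE_TARGET = 0.90


class SingleClassError(ValueError):
    """The labeled feedback set contains only one class; feedback should be
    skipped for this query."""


@dataclass
class FeedbackSet:
    """Labeled top-K retrievals for one query.

    ``features[k]`` is the coarse annular-histogram vector of item ``k``,
    ``distances[k]`` its appearance distance to the query from the initial
    retrieval, ``labels[k]`` True for relevant.  Items are stored in initial
    rank order (rank ``k+1``).
    """

    windows: list[PatchWindow]
    features: np.ndarray
    distances: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=bool)
        n = len(self.windows)
        if not (self.features.shape[0] == self.distances.shape[0] == self.labels.shape[0] == n):
            raise ValueError("windows, features, distances and labels must align")

    def __len__(self) -> int:
        return len(self.windows)

    def subset(self, idx: np.ndarray) -> "FeedbackSet":
        idx = np.asarray(idx)
        return FeedbackSet(
            [self.windows[i] for i in idx],
            self.features[idx],
            self.distances[idx],
            self.labels[idx],
        )


@dataclass
class PCABasis:
    """Fitted PCA projection retaining ``k`` components."""

    mean: np.ndarray
    components: np.ndarray           # (k, n_features)
    explained_variance_ratio: np.ndarray
    k: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) @ self.components.T


@dataclass
class FeedbackModel:
    """PCA basis plus the weighted AdaBoost stump ensemble."""

    pca: PCABasis
    stumps: list[DecisionTreeClassifier]
    alphas: np.ndarray
    initial_weights: np.ndarray

    def margin(self, X_reduced: np.ndarray) -> np.ndarray:
        """Signed ensemble score: positive means predicted relevant; the
        magnitude is the (unnormalized) weighted-vote margin."""
        X_reduced = np.atleast_2d(X_reduced)
        score = np.zeros(X_reduced.shape[0])
        for stump, a in zip(self.stumps, self.alphas):
            score += a * stump.predict(X_reduced)
        return score

    def score_features(self, features: np.ndarray) -> np.ndarray:
        return self.margin(self.pca.transform(features))


def pca_reduce(
    features: np.ndarray, variance_target: float = DEFAULT_VARIANCE_TARGET
) -> tuple[np.ndarray, PCABasis]:
    """Project ``features`` onto the smallest number of principal
    components whose cumulative explained-variance ratio reaches
    ``variance_target``.

    The PCA is fit on the feedback set itself (the on-line setting), not on
    a global corpus.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not 0 < variance_target <= 1:
        raise ValueError(f"variance_target must be in (0, 1], got {variance_target}")
    full = PCA(n_components=min(X.shape)).fit(X)
    ratios = full.explained_variance_ratio_
    # drop numerically-zero components beyond the data rank
    total = ratios.sum()
    cum = np.cumsum(ratios) / total if total > 0 else np.ones_like(ratios)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, len(ratios))
    basis = PCABasis(
        mean=full.mean_,
        components=full.components_[:k],
        explained_variance_ratio=ratios[:k],
        k=k,
    )
    return basis.transform(X), basis


def appearance_weights(distances: np.ndarray) -> np.ndarray:
    """Initial sample distribution from appearance distances.

    Distances are min-max normalized to ``D~ in [0, 1]`` (all zero when the
    distances are equal) and mapped to ``W_i proportional to (1 - D~_i) + eps``
    with ``eps = 1/K``; the floor keeps every weight positive while the
    linear decay makes ``W`` strictly decreasing in distance.  Returns a
    distribution summing to 1.
    """
    D = np.asarray(distances, dtype=np.float64)
    if D.size == 0:
        raise ValueError("appearance_weights needs at least one distance")
    if (D < 0).any():
        raise ValueError("distances must be nonnegative")
    span = D.max() - D.min()
    Dn = (D - D.min()) / span if span > 0 else np.zeros_like(D)
    W = (1.0 - Dn) + 1.0 / D.size
    return W / W.sum()


def train_weighted_adaboost(
    X: np.ndarray,
    labels: np.ndarray,
    W: np.ndarray | None = None,
    T: int = DEFAULT_ROUNDS,
    pca: PCABasis | None = None,
) -> FeedbackModel:
    """Discrete AdaBoost over decision stumps from a non-uniform start.

    Standard discrete AdaBoost, except the sample distribution is
    initialized to ``W`` (the appearance weights) instead of uniform.  Each
    round fits a depth-1 tree to the current distribution, computes the
    weighted error ``err``, the stage weight ``alpha = 0.5*ln((1-err)/err)``
    and re-weights ``D <- D * exp(-alpha * y * h(x))``.  Training stops
    early when a stump is perfect (``err == 0``) or no better than chance
    (``err >= 0.5``).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.where(np.asarray(labels, dtype=bool), 1.0, -1.0)
    if T < 1:
        raise ValueError("T must be >= 1")
    if len(np.unique(y)) < 2:
        raise SingleClassError(
            "feedback labels contain a single class; skip relevance feedback"
        )
    n = X.shape[0]
    D = np.full(n, 1.0 / n) if W is None else np.asarray(W, dtype=np.float64).copy()
    if D.shape[0] != n or (D <= 0).any():
        raise ValueError("W must be a positive distribution over the samples")
    D = D / D.sum()

    stumps: list[DecisionTreeClassifier] = []
    alphas: list[float] = []
    W0 = D.copy()
    for t in range(T):
        stump = DecisionTreeClassifier(max_depth=1, random_state=0)
        stump.fit(X, y, sample_weight=D)
        pred = stump.predict(X)
        err = float(D[pred != y].sum())
        if err >= 0.5:
            if not stumps:  # keep something: a chance-level model
                stumps.append(stump)
                alphas.append(0.0)
            break
        if err == 0.0:
            stumps.append(stump)
            # cap the stage weight of a perfect stump instead of +inf
            alphas.append(0.5 * np.log((1.0 - 1e-10) / 1e-10))
            break
        alpha = 0.5 * np.log((1.0 - err) / err)
        stumps.append(stump)
        alphas.append(alpha)
        D = D * np.exp(-alpha * y * pred)
        D /= D.sum()
    return FeedbackModel(
        pca=pca, stumps=stumps, alphas=np.asarray(alphas), initial_weights=W0
    )


def train_feedback(
    items: FeedbackSet,
    variance_target: float = DEFAULT_VARIANCE_TARGET,
    T: int = DEFAULT_ROUNDS,
) -> FeedbackModel:
    """Full feedback training: PCA reduction of the item features, then
    appearance-weighted AdaBoost on the labels."""
    Xr, basis = pca_reduce(items.features, variance_target)
    W = appearance_weights(items.distances)
    return train_weighted_adaboost(Xr, items.labels, W, T=T, pca=basis)


def rerank(model: FeedbackModel, items: FeedbackSet) -> RankedCandidates:
    """Re-order the feedback set by descending ensemble margin.

    Ties are broken by the original rank, so a degenerate model (e.g. a
    single stump voting "relevant" everywhere) preserves the initial
    ordering.  The returned distances are the negated margins, keeping the
    ascending-distance convention of :class:`RankedCandidates`.
    """
    if model.pca is not None:
        scores = model.score_features(items.features)
    else:
        scores = model.margin(items.features)
    order = sorted(range(len(items)), key=lambda k: (-scores[k], k))
    entries = [(items.windows[k], float(-scores[k])) for k in order]
    return RankedCandidates(entries, stage="feedback", query=None,
                            stats={"margins": [float(scores[k]) for k in order]})
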
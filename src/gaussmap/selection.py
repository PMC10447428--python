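"""Fisher-score feature ranking and selection.

The Fisher score of a feature dimension is its between-class scatter over
its within-class scatter,

    F_j = sum_c n_c (mu_cj - mu_j)^2  /  sum_c n_c var_cj

with population (n_c-denominator) class variances. For two balanced classes
this reduces to the familiar (mu_1 - mu_2)^2 / (sigma_1^2 + sigma_2^2) up to
class-size weighting. Dimensions are ranked by descending score; selection
is always fitted on training data only and re-applied to test data
(out-of-fold selection inflates accuracy estimates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin


class DegenerateLabelsError(ValueError):
    """Fisher score needs at least two classes."""


@dataclass
class FisherRanking:
    """Per-dimension Fisher scores, the descending-score order, and k."""

    scores: np.ndarray
    order: np.ndarray
    k: int | None = None


def fisher_score(X: np.ndarray, y) -> FisherRanking:
    """Rank feature dimensions of X (subjects x features) by Fisher score.

    Zero within-class variance with nonzero between-class spread is a
    perfectly separating dimension and scores +inf (ranked first); zero
    within- and between-class spread scores 0. Ties break by ascending
    dimension index (np.argsort stable order on the negated scores).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateLabelsError("need >= 2 classes for Fisher score")
    mu = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        n_c = len(Xc)
        if n_c < 2:
            raise DegenerateLabelsError(f"class {c!r} has < 2 subjects")
        mu_c = Xc.mean(axis=0)
        between += n_c * (mu_c - mu) ** 2
        within += n_c * Xc.var(axis=0)  # population variance
    scale = np.maximum(np.abs(X).max(axis=0), 1.0) ** 2
    zero_within = within <= 1e-24 * scale
    scores = np.empty(X.shape[1])
    nz = ~zero_within
    scores[nz] = between[nz] / within[nz]
    scores[zero_within] = np.where(between[zero_within] > 1e-24 * scale[zero_within],
                                   np.inf, 0.0)
    order = np.argsort(-scores, kind="stable")
    return FisherRanking(scores=scores, order=order)


def select_top(ranking: FisherRanking, k: int, X: np.ndarray) -> np.ndarray:
    """Keep the k best-ranked columns of X, in ranking order."""
    if not 1 <= k <= X.shape[1]:
        raise ValueError(f"k must be in [1, {X.shape[1]}], got {k}")
    ranking.k = k
    return np.asarray(X)[:, ranking.order[:k]]


class FisherSelector(BaseEstimator, TransformerMixin):
    """sklearn transformer wrapper so selection lives inside CV pipelines.

    k=None keeps all dimensions (still reordered by rank, which is harmless
    for the downstream kernel).
    """

    def __init__(self, k: int | None = None):
        self.k = k

    def fit(self, X, y):
        self.ranking_ = fisher_score(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        k = self.k if self.k is not None else self.n_features_in_
        k = min(k, self.n_features_in_)
        return np.asarray(X)[:, self.ranking_.order[:k]]
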
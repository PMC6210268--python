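"""Multiclass ReliefF feature weighting and ranking.

ReliefF scores a feature by how well it separates each pivot instance from
its nearest neighbours of other classes (misses) relative to its nearest
neighbours of the same class (hits). For pivot R with k hits H and, per
other class C with prior P(C), k misses M_C, the weight of feature f is
updated by

    W[f] -= sum_H diff(f, R, H) / (m k)
    W[f] += sum_{C != class(R)} P(C)/(1 - P(class(R)))
            * sum_{M_C} diff(f, R, M_C) / (m k)

over m pivots, with diff the absolute difference range-normalised by the
global per-feature (max - min), so every weight lies in [-1, 1].

Conventions: instances are compared by Manhattan distance on the
range-normalised features; neighbour-distance ties break by instance index;
by default every instance serves as a pivot (fully deterministic) and the
neighbour count is k = 100, clipped per class with a warning when a class
is too small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class FeatureRanking:
    """Descending-weight ordering of features with 1-based ranks."""

    entries: list  # (feature_name, weight, rank)
    n_neighbors: int = 0
    n_sampled: int = 0

    @property
    def names(self) -> list[str]:
        return [e[0] for e in self.entries]

    def top_n(self, n: int) -> list[str]:
        if not (1 <= n <= len(self.entries)):
            raise ValueError(
                f"n must lie in [1, {len(self.entries)}], got {n}"
            )
        return self.names[:n]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r, f, w) for f, w, r in self.entries],
            columns=["rank", "feature", "weight"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureRanking":
        df = pd.read_csv(path).sort_values("rank")
        return cls([(f, w, int(r)) for r, f, w in
                    df[["rank", "feature", "weight"]].itertuples(index=False)])


class ReliefFSelector(SelectorMixin, BaseEstimator):
    """Multiclass ReliefF feature selector.

    Parameters
    ----------
    n_neighbors : neighbour count k for hits and per-class misses.
    n_features_to_select : features kept by :meth:`transform`.
    n_sampled : number of pivot instances, or None for all (deterministic).
    random_state : seed for pivot subsampling (ignored when exhaustive).

    Attributes
    ----------
    weights_ : ReliefF weight per feature, in [-1, 1].
    ranking_ : 1-based rank per feature (1 = most relevant).
    """

    def __init__(self, n_neighbors: int = 100,
                 n_features_to_select: int = 10,
                 n_sampled: int | None = None,
                 random_state: int | None = None):
        self.n_neighbors = n_neighbors
        self.n_features_to_select = n_features_to_select
        self.n_sampled = n_sampled
        self.random_state = random_state

    def fit(self, X, y) -> "ReliefFSelector":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, p = X.shape
        classes, y_idx = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            raise ValueError("ReliefF requires at least 2 classes")
        counts = np.bincount(y_idx)
        if counts.min() < 2:
            raise ValueError("every class needs at least 2 instances")

        rng_range = X.max(axis=0) - X.min(axis=0)
        zero_range = rng_range == 0
        if zero_range.any():
            warnings.warn(
                "features with zero range receive weight 0: "
                f"{int(zero_range.sum())} affected"
            )
        safe_range = np.where(zero_range, 1.0, rng_range)
        Xn = (X - X.min(axis=0)) / safe_range
        Xn[:, zero_range] = 0.0

        priors = counts / n
        D = cdist(Xn, Xn, metric="cityblock")

        if self.n_sampled is None or self.n_sampled >= n:
            pivots = np.arange(n)
        else:
            rng = np.random.default_rng(self.random_state)
            pivots = np.sort(
                rng.choice(n, size=self.n_sampled, replace=False)
            )
        m = len(pivots)

        max_k = counts.min() - 1
        k = self.n_neighbors
        if k > max_k:
            warnings.warn(
                f"n_neighbors={k} exceeds the smallest class; clipping to {max_k}"
            )
        class_members = [np.flatnonzero(y_idx == c) for c in range(len(classes))]

        W = np.zeros(p)
        for r in pivots:
            cr = y_idx[r]
            for c, members in enumerate(class_members):
                cand = members[members != r]
                kk = min(k, len(cand))
                order = np.argsort(D[r, cand], kind="stable")[:kk]
                nbrs = cand[order]
                diffs = np.abs(Xn[r] - Xn[nbrs]).sum(axis=0)
                if c == cr:
                    W -= diffs / (m * kk)
                else:
                    W += (priors[c] / (1.0 - priors[cr])) * diffs / (m * kk)

        self.classes_ = classes
        self.n_features_in_ = p
        self.weights_ = W
        order = self._rank_order(W)
        self.ranking_ = np.empty(p, dtype=int)
        self.ranking_[order] = np.arange(1, p + 1)
        self.top_indices_ = order
        return self

    @staticmethod
    def _rank_order(weights: np.ndarray,
                    names: list[str] | None = None) -> np.ndarray:
        """Indices in descending-weight order; ties break lexicographically
        by feature name (or by index when unnamed)."""
        if names is None:
            names = [str(i) for i in range(len(weights))]
            keys = np.arange(len(weights))
        else:
            keys = np.argsort(np.argsort(names, kind="stable"), kind="stable")
        return np.lexsort((keys, -np.asarray(weights)))

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "weights_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.top_indices_[: self.n_features_to_select]] = True
        return mask


def relieff_weights(X, y, n_neighbors: int = 100,
                    n_sampled: int | None = None,
                    seed: int | None = None) -> dict[str, float]:
    """ReliefF weight for each feature of a feature matrix.

    ``X`` may be a DataFrame (feature names from columns) or an array
    (features named by position).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        values = X.to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(values.shape[1])]
    sel = ReliefFSelector(n_neighbors=n_neighbors, n_sampled=n_sampled,
                          random_state=seed).fit(values, y)
    return dict(zip(names, sel.weights_))


def rank_features(weights: dict[str, float], n_neighbors: int = 0,
                  n_sampled: int = 0) -> FeatureRanking:
    """Order features by descending weight; ties break lexicographically."""
    if not weights:
        raise ValueError("empty weight map")
    ordered = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    return FeatureRanking(
        [(name, w, i + 1) for i, (name, w) in enumerate(ordered)],
        n_neighbors=n_neighbors, n_sampled=n_sampled,
    )


def top_n(ranking: FeatureRanking, n: int) -> list[str]:
    """The first n feature names in rank order."""
    return ranking.top_n(n)
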
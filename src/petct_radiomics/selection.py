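"""Minimum-redundancy-maximum-relevance feature ranking and scree cutoff.

MRMR greedy forward selection under the difference (MID) criterion: at each
step the feature maximizing

    I(f; y) - mean_{s in selected} I(f; s)

is added, where mutual information is the plug-in estimate (base 2) after
discretizing each continuous feature into 4 equal-frequency bins (discrete
features are used as-is).  Ties break by table column order.  The retained
count k is chosen at the elbow of the ranked score curve: the rank whose
point is farthest (perpendicular distance) from the chord joining the first
and last points after min-max normalizing both axes.

Equal-frequency binning makes the ranking invariant to strictly monotone
transforms of continuous features; axis normalization makes the elbow
invariant to affine rescaling of the scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["SelectionResult", "mrmr_rank", "scree_cutoff", "MRMRSelector"]

_COLLINEAR_TOL = 1e-9
_FALLBACK_MAX_K = 10


@dataclass(frozen=True)
class SelectionResult:
    ranked_features: list
    scores: np.ndarray
    k: int | None = None

    def top(self, k: int | None = None) -> list:
        k = self.k if k is None else k
        if k is None:
            raise ValueError("no k set on this SelectionResult")
        return list(self.ranked_features[:k])


def _discretize(X: pd.DataFrame, discrete_columns, n_bins: int) -> np.ndarray:
    discrete = set(discrete_columns)
    arr = X.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        k = int(np.argmax(~np.isfinite(arr).all(axis=0)))
        raise ValueError(f"non-finite values in column {X.columns[k]!r}; impute first")
    # vectorized equal-frequency codes: count of bin edges <= x, per column
    qs = np.quantile(arr, [q / n_bins for q in range(1, n_bins)], axis=0, method="lower")
    codes = (arr[:, :, None] >= qs.T[None, :, :]).sum(axis=2).astype(np.int64)
    for k, col in enumerate(X.columns):
        if col in discrete:
            codes[:, k] = np.unique(arr[:, k], return_inverse=True)[1]
    return codes


def _mi_from_counts(counts: np.ndarray) -> np.ndarray:
    """MI (bits) for a stack of contingency tables, shape (..., a, b)."""
    n = counts.sum(axis=(-2, -1), keepdims=True)
    p = counts / n
    px = p.sum(axis=-1, keepdims=True)
    py = p.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log2(p / (px * py))
    return np.nansum(term, axis=(-2, -1))


def _pairwise_mi(codes: np.ndarray, other: np.ndarray, base: int) -> np.ndarray:
    """MI between each column of ``codes`` and the single code vector
    ``other`` (values < base)."""
    n, p = codes.shape
    joint = codes * base + other[:, None]
    flat = joint + np.arange(p) * (base * base)
    counts = np.bincount(flat.ravel(), minlength=p * base * base)
    return _mi_from_counts(counts.reshape(p, base, base).astype(float))


def mrmr_rank(
    X: pd.DataFrame,
    y,
    max_rank: int | None = None,
    discrete_columns=(),
    n_bins: int = 4,
) -> SelectionResult:
    """Greedy MRMR ranking of the columns of X against binary labels y.

    Returns ranked feature names with the per-rank MRMR objective value
    (relevance minus mean redundancy at the moment of selection); ``k`` is
    left unset (see :func:`scree_cutoff`).
    """
    y = np.asarray(y, dtype=np.int64)
    classes, y_codes = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("labels are constant; MRMR requires both classes")
    if np.bincount(y_codes).min() < 2:
        raise ValueError("need at least 2 rows per class")
    m = X.shape[1]
    if max_rank is None:
        max_rank = m
    if max_rank < 1:
        raise ValueError(f"max_rank must be >= 1, got {max_rank}")
    max_rank = min(max_rank, m)

    codes = _discretize(X, discrete_columns, n_bins)
    base = int(max(codes.max() + 1, n_bins, classes.size))
    relevance = _pairwise_mi(codes, y_codes.astype(np.int64), base)

    selected: list[int] = []
    scores: list[float] = []
    red_sum = np.zeros(m)
    available = np.ones(m, dtype=bool)
    for _ in range(max_rank):
        objective = np.where(
            available,
            relevance - (red_sum / len(selected) if selected else 0.0),
            -np.inf,
        )
        # round so mathematically tied objectives (e.g. permuted contingency
        # tables) are not separated by float-summation noise; ties then
        # resolve to the lowest column index
        objective = np.round(objective, 10)
        pick = int(np.argmax(objective))
        scores.append(float(objective[pick]))
        selected.append(pick)
        available[pick] = False
        if len(selected) < max_rank:
            red_sum += _pairwise_mi(codes, codes[:, pick], base)
    return SelectionResult(
        ranked_features=[X.columns[i] for i in selected],
        scores=np.asarray(scores),
    )


def scree_cutoff(scores) -> int:
    """Elbow of a ranked score curve by maximum chord distance.

    Both axes are min-max normalized; k is the rank farthest from the chord
    joining the first and last points.  If the curve is numerically
    collinear the fallback is ``min(10, m)``; a single score gives k = 1.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty score vector")
    m = s.size
    if m == 1:
        return 1
    x = np.arange(m) / (m - 1)
    span = s.max() - s.min()
    if span <= 0:
        return min(_FALLBACK_MAX_K, m)
    ynorm = (s - s.min()) / span
    # distance from (x, y) to the chord through the first and last points
    dx, dy = x[-1] - x[0], ynorm[-1] - ynorm[0]
    dist = np.abs(dy * (x - x[0]) - dx * (ynorm - ynorm[0])) / np.hypot(dx, dy)
    if dist.max() <= _COLLINEAR_TOL:
        return min(_FALLBACK_MAX_K, m)
    return int(np.argmax(dist)) + 1


class MRMRSelector(TransformerMixin, BaseEstimator):
    """scikit-learn transformer: MRMR ranking + scree-cutoff column subset.

    Parameters
    ----------
    k : int or "scree"
        Retained feature count; "scree" chooses the elbow of the score curve.
    max_rank : int or None
        Depth of the greedy ranking (None = all columns).
    discrete_columns : columns used as-is (no quantile binning).
    n_bins : equal-frequency bin count for continuous features.

    Fitted attributes: ``ranking_`` (ordered names), ``scores_``, ``k_``,
    ``selected_features_``.
    """

    def __init__(self, k="scree", max_rank=None, discrete_columns=(), n_bins=4):
        self.k = k
        self.max_rank = max_rank
        self.discrete_columns = discrete_columns
        self.n_bins = n_bins

    def fit(self, X: pd.DataFrame, y):
        result = mrmr_rank(
            X,
            y,
            max_rank=self.max_rank,
            discrete_columns=self.discrete_columns,
            n_bins=self.n_bins,
        )
        self.ranking_ = result.ranked_features
        self.scores_ = result.scores
        self.k_ = scree_cutoff(result.scores) if self.k == "scree" else int(self.k)
        self.k_ = min(self.k_, len(self.ranking_))
        self.selected_features_ = list(self.ranking_[: self.k_])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_features_]
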
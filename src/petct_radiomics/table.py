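"""Unified per-patient feature table and harmonization (imputation).

The table joins, per patient: 242 CT radiomic features, 242 PET radiomic
features, the three PET metrics, and clinical covariates, with the binary
early-progression label.  Harmonization first converts every non-finite
entry (NaN or infinity) to missing, then fills continuous columns with the
feature-wise mean of observed values and discrete columns with the
feature-wise median (even count -> lower-middle value).

``TableImputer`` is a scikit-learn transformer so the fill statistics can
be fit on training rows only inside cross-validation and applied to held-out
rows; :func:`impute` applies the literal whole-table behavior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .texture import feature_names

__all__ = ["FeatureTable", "assemble", "impute", "TableImputer", "DISCRETE_CLINICAL"]

DISCRETE_CLINICAL = ("sex", "location", "resectability")
_CLINICAL_ORDER = ("age", "sex", "location", "ca199", "resectability")


@dataclass
class FeatureTable:
    """Per-patient features, per-column kind tags, and labels.

    ``features`` is id-indexed; ``kinds`` maps column -> "continuous" |
    "discrete"; ``labels`` is the binary EP label aligned to the rows.
    """

    features: pd.DataFrame
    labels: pd.Series
    kinds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.features.index.has_duplicates:
            raise ValueError("duplicate patient ids in feature table")
        if not self.features.index.equals(self.labels.index):
            raise ValueError("labels index does not match feature rows")
        missing_kinds = [c for c in self.features.columns if c not in self.kinds]
        for c in missing_kinds:
            self.kinds[c] = "continuous"

    @property
    def discrete_columns(self) -> list:
        return [c for c in self.features.columns if self.kinds[c] == "discrete"]

    def subset(self, ids) -> "FeatureTable":
        return FeatureTable(
            features=self.features.loc[ids],
            labels=self.labels.loc[ids],
            kinds=dict(self.kinds),
        )


def assemble(
    image_features: pd.DataFrame,
    pet_metrics: pd.DataFrame,
    clinical: pd.DataFrame,
) -> FeatureTable:
    """Join image features, PET metrics and clinical covariates by id.

    All three inputs must be indexed by the same id set; ``clinical`` must
    contain the ``label`` column.  Column order is CT_* (242), PET_* (242),
    suvmax, mtv_cc, tlg, then clinical covariates.
    """
    ids = image_features.index
    for name, df in (("pet_metrics", pet_metrics), ("clinical", clinical)):
        if set(df.index) != set(ids):
            only_img = sorted(set(map(str, set(ids) - set(df.index))))
            only_other = sorted(set(map(str, set(df.index) - set(ids))))
            raise ValueError(
                f"id mismatch with {name}: missing {only_img}, extra {only_other}"
            )
    if len(ids) == 0:
        raise ValueError("empty id set")
    cols = feature_names("CT") + feature_names("PET")
    img = image_features.loc[ids, cols]
    met = pet_metrics.loc[ids, ["suvmax", "mtv_cc", "tlg"]]
    clin_cols = [c for c in _CLINICAL_ORDER if c in clinical.columns]
    clin = clinical.loc[ids, clin_cols].astype(float)
    features = pd.concat([img, met, clin], axis=1)
    kinds = {c: "continuous" for c in features.columns}
    for c in DISCRETE_CLINICAL:
        if c in kinds:
            kinds[c] = "discrete"
    labels = clinical.loc[ids, "label"].astype(int)
    labels.name = "label"
    return FeatureTable(features=features, labels=labels, kinds=kinds)


def _lower_median(x: np.ndarray) -> float:
    xs = np.sort(x)
    return float(xs[(xs.size - 1) // 2])


class TableImputer(TransformerMixin, BaseEstimator):
    """Feature-wise mean/median imputer with non-finite-to-missing handling.

    Parameters
    ----------
    discrete_columns : sequence of column names filled with the lower-middle
        median of observed values; all other columns use the mean.

    Fitted attributes
    -----------------
    fill_values_ : pandas.Series of per-column fill statistics.
    all_missing_columns_ : columns with no observed value, filled with 0
        (reported via a warning at fit time).
    """

    def __init__(self, discrete_columns=()):
        self.discrete_columns = discrete_columns

    def fit(self, X: pd.DataFrame, y=None):
        discrete = set(self.discrete_columns)
        arr = X.to_numpy(dtype=float, copy=True)
        arr[~np.isfinite(arr)] = np.nan
        n_obs = (~np.isnan(arr)).sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            fills = np.nanmean(arr, axis=0)
        fills[n_obs == 0] = 0.0
        all_missing = [c for c, n in zip(X.columns, n_obs) if n == 0]
        for k, col in enumerate(X.columns):
            if col in discrete and n_obs[k] > 0:
                fills[k] = _lower_median(arr[~np.isnan(arr[:, k]), k])
        self.fill_values_ = pd.Series(fills, index=X.columns)
        self.all_missing_columns_ = all_missing
        self.n_features_in_ = X.shape[1]
        if all_missing:
            warnings.warn(
                f"{len(all_missing)} fully-missing column(s) filled with 0: "
                f"{all_missing[:5]}{'...' if len(all_missing) > 5 else ''}",
                stacklevel=2,
            )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        arr = X.to_numpy(dtype=float, copy=True)
        bad = ~np.isfinite(arr)
        if bad.any():
            fills = self.fill_values_.reindex(X.columns).to_numpy()
            arr[bad] = np.broadcast_to(fills, arr.shape)[bad]
        return pd.DataFrame(arr, index=X.index, columns=X.columns)


def impute(table: FeatureTable) -> FeatureTable:
    """Harmonize a table in place of CV: fill statistics from the supplied
    rows themselves (the literal whole-table behavior)."""
    imputer = TableImputer(discrete_columns=table.discrete_columns)
    filled = imputer.fit(table.features).transform(table.features)
    return FeatureTable(features=filled, labels=table.labels, kinds=dict(table.kinds))
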
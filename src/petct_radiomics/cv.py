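"""Nested stratified cross-validation of the full radiomics pipeline.

The outer 10-fold CV provides the test folds; within each outer fold an
inner 5-fold CV performs, per inner split and without any access to the
outer test rows: imputation (statistics fit on the inner training rows),
MRMR ranking with a scree cutoff, cascade training over the hyperparameter
grid, and ROC tuning of the stage-2 operating threshold on the inner
validation rows.  The grid point with the best mean inner validation
accuracy wins; the cascade is then retrained on the full outer-training set
(train + validation) with the retained-feature count fixed to the median
inner scree k, features re-ranked on the outer-training rows, and theta
frozen to the mean of the inner tuned thetas.  Predictions over all outer
test folds are pooled into one confusion matrix, accuracy and rank-based
AUC; fold-wise accuracy mean and a normal-approximation 95% CI half-width
are also reported.
"""

from __future__ import annotations

import logging
import time
from collections import Counter
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cascade import CascadeDecisionTreeClassifier
from .selection import MRMRSelector
from .table import FeatureTable, TableImputer, impute as impute_table

__all__ = [
    "FoldPlan",
    "CVConfig",
    "CVReport",
    "make_folds",
    "run_nested_cv",
    "auc",
    "confusion_and_accuracy",
    "DEFAULT_GRID",
]

logger = logging.getLogger(__name__)

#: hyperparameter grid searched in the inner CV
DEFAULT_GRID = tuple(
    {"c_low": 1.0, "c_high": ch, "max_depth": d}
    for ch in (2.0, 3.0, 5.0)
    for d in (2, 3, 4)
)


@dataclass(frozen=True)
class FoldPlan:
    """Stratified outer folds and, per outer fold, inner folds over the rest."""

    outer_folds: list
    inner_folds: list  # inner_folds[t][j] = id array for inner fold j of outer fold t
    seed: int


@dataclass
class CVConfig:
    k_outer: int = 10
    k_inner: int = 5
    max_rank: int = 30
    n_bins: int = 4
    reliability_tau: float = 0.5
    global_impute: bool = False
    metric: str = "accuracy"  # or "balanced_accuracy"
    random_state: int = 0


@dataclass
class CVReport:
    folds: list = field(default_factory=list)
    predictions: pd.DataFrame | None = None
    confusion: dict | None = None
    accuracy: float | None = None
    auc: float | None = None
    roc_points: list = field(default_factory=list)
    fold_accuracy_mean: float | None = None
    fold_accuracy_ci_half_width: float | None = None
    selection_frequency: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["predictions"] = (
            self.predictions.to_dict(orient="list") if self.predictions is not None else None
        )
        return d


def _deal_stratified(ids, labels, k, rng) -> list:
    """Shuffle within class, then deal round-robin: fold sizes and per-class
    counts each differ by at most one."""
    ids = np.asarray(ids)
    labels = np.asarray(labels)
    order = []
    for cls in (1, 0):
        members = ids[labels == cls]
        order.extend(rng.permutation(members).tolist())
    folds = [[] for _ in range(k)]
    for pos, pid in enumerate(order):
        folds[pos % k].append(pid)
    return [np.asarray(f) for f in folds]


def make_folds(labels: pd.Series, k_outer: int = 10, k_inner: int = 5, seed: int = 0,
               max_redraws: int = 5) -> FoldPlan:
    """Build the stratified outer/inner fold plan.

    ``labels`` is an id-indexed binary series.  Requires at least ``k_outer``
    members of each class.  Inner splits with a single-class training or
    validation side are re-drawn with an incremented substream (logged, at
    most ``max_redraws`` attempts).
    """
    y = labels.astype(int)
    counts = y.value_counts()
    if counts.min() < k_outer or counts.size < 2:
        raise ValueError(
            f"each class needs >= {k_outer} members for {k_outer}-fold stratified "
            f"CV (got {dict(counts)}); use a smaller k_outer"
        )
    ids = np.asarray(y.index)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    outer = _deal_stratified(ids, y.to_numpy(), k_outer, rng)
    inner_all = []
    for t, test_ids in enumerate(outer):
        rest = np.setdiff1d(ids, test_ids, assume_unique=True)
        rest_y = y.loc[rest].to_numpy()
        for attempt in range(max_redraws):
            rng_t = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(t + 1, attempt))
            )
            inner = _deal_stratified(rest, rest_y, k_inner, rng_t)
            ok = all(
                np.unique(y.loc[f]).size == 2
                and np.unique(y.loc[np.setdiff1d(rest, f, assume_unique=True)]).size == 2
                for f in inner
            )
            if ok:
                if attempt:
                    logger.info("outer fold %d: inner folds re-drawn %d time(s)", t, attempt)
                break
        else:
            raise ValueError(
                f"could not draw non-degenerate inner folds for outer fold {t} "
                f"after {max_redraws} attempts"
            )
        inner_all.append(inner)
    return FoldPlan(outer_folds=outer, inner_folds=inner_all, seed=seed)


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted 1/2."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_and_accuracy(predictions, labels):
    """2x2 confusion counts and accuracy."""
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    if pred.shape != y.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {y.shape}")
    cm = {
        "tp": int(((pred == 1) & (y == 1)).sum()),
        "fn": int(((pred == 0) & (y == 1)).sum()),
        "fp": int(((pred == 1) & (y == 0)).sum()),
        "tn": int(((pred == 0) & (y == 0)).sum()),
    }
    return cm, (cm["tp"] + cm["tn"]) / y.size


def _score(pred, y, metric: str) -> float:
    if metric == "balanced_accuracy":
        from sklearn.metrics import balanced_accuracy_score

        return float(balanced_accuracy_score(y, pred))
    return float((np.asarray(pred) == np.asarray(y)).mean())


def _lower_median_int(values) -> int:
    v = sorted(values)
    return int(v[(len(v) - 1) // 2])


def run_nested_cv(
    table: FeatureTable,
    fold_plan: FoldPlan | None = None,
    grid=DEFAULT_GRID,
    config: CVConfig | None = None,
) -> CVReport:
    """Run the full nested CV over a harmonizable feature table."""
    config = config or CVConfig()
    if fold_plan is None:
        fold_plan = make_folds(
            table.labels, config.k_outer, config.k_inner, seed=config.random_state
        )
    if config.global_impute:
        table = impute_table(table)
    discrete = table.discrete_columns
    all_ids = np.asarray(table.labels.index)

    report = CVReport()
    frames = []
    fold_accuracies = []
    freq: Counter = Counter()
    for t, test_ids in enumerate(fold_plan.outer_folds):
        t0 = time.perf_counter()
        train_ids = np.setdiff1d(all_ids, test_ids, assume_unique=True)
        inner = fold_plan.inner_folds[t]

        # per-inner-split selection artefacts (shared across grid points)
        splits = []
        for val_ids in inner:
            trn_ids = np.setdiff1d(train_ids, val_ids, assume_unique=True)
            imputer = TableImputer(discrete_columns=discrete)
            Xtr = imputer.fit(table.features.loc[trn_ids]).transform(
                table.features.loc[trn_ids]
            )
            Xval = imputer.transform(table.features.loc[val_ids])
            sel = MRMRSelector(
                max_rank=config.max_rank,
                discrete_columns=discrete,
                n_bins=config.n_bins,
            ).fit(Xtr, table.labels.loc[trn_ids])
            splits.append(
                {
                    "Xtr": sel.transform(Xtr),
                    "ytr": table.labels.loc[trn_ids].to_numpy(),
                    "Xval": sel.transform(Xval),
                    "yval": table.labels.loc[val_ids].to_numpy(),
                    "k": sel.k_,
                }
            )

        best = None
        for g, params in enumerate(grid):
            accs, thetas = [], []
            for s in splits:
                clf = CascadeDecisionTreeClassifier(
                    reliability_tau=config.reliability_tau,
                    random_state=config.random_state,
                    **params,
                ).fit(s["Xtr"], s["ytr"])
                thetas.append(clf.tune_operating_point(s["Xval"], s["yval"]))
                accs.append(_score(clf.predict(s["Xval"]), s["yval"], config.metric))
            mean_acc = float(np.mean(accs))
            if best is None or mean_acc > best["acc"]:
                best = {"acc": mean_acc, "params": params, "thetas": thetas}

        k_final = _lower_median_int([s["k"] for s in splits])
        theta_final = float(np.mean(best["thetas"]))

        # final refit on the combined training + validation rows
        imputer = TableImputer(discrete_columns=discrete)
        Xtrain = imputer.fit(table.features.loc[train_ids]).transform(
            table.features.loc[train_ids]
        )
        Xtest = imputer.transform(table.features.loc[test_ids])
        sel = MRMRSelector(
            k=k_final,
            max_rank=max(config.max_rank, k_final),
            discrete_columns=discrete,
            n_bins=config.n_bins,
        ).fit(Xtrain, table.labels.loc[train_ids])
        clf = CascadeDecisionTreeClassifier(
            reliability_tau=config.reliability_tau,
            operating_theta=theta_final,
            random_state=config.random_state,
            **best["params"],
        ).fit(sel.transform(Xtrain), table.labels.loc[train_ids])
        labels, probs, stages = clf.predict_detail(sel.transform(Xtest))
        y_test = table.labels.loc[test_ids].to_numpy()

        frames.append(
            pd.DataFrame(
                {
                    "id": test_ids,
                    "fold": t,
                    "label": y_test,
                    "prediction": labels,
                    "prob": probs,
                    "stage": stages,
                }
            )
        )
        fold_accuracies.append(float((labels == y_test).mean()))
        freq.update(sel.selected_features_)
        report.folds.append(
            {
                "fold": t,
                "selected_features": list(sel.selected_features_),
                "split_features": sorted(map(str, clf.split_feature_names())),
                "hyperparams": dict(best["params"]),
                "k": k_final,
                "theta": theta_final,
                "inner_accuracy": best["acc"],
                "test_accuracy": fold_accuracies[-1],
            }
        )
        logger.info(
            "outer fold %d: params=%s k=%d theta=%.3f acc=%.3f (%.2fs)",
            t, best["params"], k_final, theta_final, fold_accuracies[-1],
            time.perf_counter() - t0,
        )

    pred = pd.concat(frames, ignore_index=True)
    report.predictions = pred
    report.confusion, report.accuracy = confusion_and_accuracy(
        pred["prediction"], pred["label"]
    )
    report.auc = auc(pred["prob"], pred["label"])
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(pred["label"], pred["prob"])
    report.roc_points = list(zip(fpr.tolist(), tpr.tolist()))
    accs = np.asarray(fold_accuracies)
    report.fold_accuracy_mean = float(accs.mean())
    report.fold_accuracy_ci_half_width = float(
        1.96 * accs.std(ddof=1) / np.sqrt(accs.size)
    )
    report.selection_frequency = dict(freq)
    return report
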
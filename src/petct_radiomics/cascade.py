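"""Two-level cost-sensitive decision-tree cascade.

Two CART trees are grown on the same rows with different false-negative
costs, realized as a class weight on the positive class: the low-cost tree
gives a first, lenient read; if its predicted-class leaf probability
exceeds the reliability threshold tau (strictly) the prediction is accepted,
otherwise the sample is deferred to the high-cost tree, which decides by
comparing its positive-class probability to a ROC-tuned operating threshold
theta.  Leaf probabilities are weighted class frequencies.

The fitted model serializes to JSON (split feature, threshold, children,
weighted leaf counts) with bit-exact prediction round-trip; prediction
always traverses the serialized-form node arrays, so a model loaded from
JSON behaves identically to a freshly fitted one.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = ["CascadeDecisionTreeClassifier", "tune_operating_point"]


class _Tree:
    """Flat node-array binary tree: x[feature] <= threshold goes left."""

    __slots__ = ("feature", "threshold", "left", "right", "pos_prob")

    def __init__(self, feature, threshold, left, right, pos_prob):
        self.feature = np.asarray(feature, dtype=np.int64)
        self.threshold = np.asarray(threshold, dtype=float)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.pos_prob = np.asarray(pos_prob, dtype=float)

    @classmethod
    def from_sklearn(cls, clf: DecisionTreeClassifier, classes: np.ndarray) -> "_Tree":
        t = clf.tree_
        value = t.value.reshape(t.node_count, -1)  # weighted class fractions
        pos_col = int(np.where(classes == 1)[0][0]) if 1 in classes else None
        if pos_col is None:
            raise ValueError("positive class 1 absent from fitted tree")
        pos = value[:, pos_col] / value.sum(axis=1)
        return cls(t.feature, t.threshold, t.children_left, t.children_right, pos)

    def predict_pos_prob(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            node = 0
            while self.left[node] != -1:
                if row[self.feature[node]] <= self.threshold[node]:
                    node = self.left[node]
                else:
                    node = self.right[node]
            out[i] = self.pos_prob[node]
        return out

    def split_features(self) -> set[int]:
        return set(self.feature[self.left != -1].tolist())

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "pos_prob": self.pos_prob.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Tree":
        return cls(d["feature"], d["threshold"], d["left"], d["right"], d["pos_prob"])


def _as_array(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [f for f in feature_names if f not in X.columns]
            if missing:
                raise ValueError(f"missing feature(s): {missing}")
            X = X[list(feature_names)]
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


class CascadeDecisionTreeClassifier(ClassifierMixin, BaseEstimator):
    """Two-stage cost-sensitive decision-tree classifier.

    Parameters
    ----------
    c_low, c_high : float
        False-negative cost (positive-class weight) of the first and second
        stage; requires ``c_high > c_low >= 1`` (equality is tolerated and
        degenerates to a single tree).
    max_depth : int
        Depth cap of both trees.
    reliability_tau : float in (0, 1)
        Stage-1 acceptance threshold on the predicted-class leaf
        probability (strict inequality).
    operating_theta : float in [0, 1]
        Stage-2 positive-decision threshold on the positive-class
        probability (inclusive), normally set by
        :meth:`tune_operating_point`.
    random_state : int
        Seed for tree tie-breaking.
    """

    def __init__(
        self,
        c_low: float = 1.0,
        c_high: float = 3.0,
        max_depth: int = 3,
        reliability_tau: float = 0.5,
        operating_theta: float = 0.5,
        random_state: int = 0,
    ):
        self.c_low = c_low
        self.c_high = c_high
        self.max_depth = max_depth
        self.reliability_tau = reliability_tau
        self.operating_theta = operating_theta
        self.random_state = random_state

    def _validate_params_values(self):
        if not self.c_low >= 1:
            raise ValueError(f"c_low must be >= 1, got {self.c_low}")
        if self.c_high < self.c_low:
            raise ValueError(
                f"c_high ({self.c_high}) must be >= c_low ({self.c_low})"
            )
        if not 0.0 <= self.reliability_tau <= 1.0:
            raise ValueError(f"reliability_tau must be in [0, 1], got {self.reliability_tau}")
        if not 0.0 <= self.operating_theta <= 1.0:
            raise ValueError(f"operating_theta must be in [0, 1], got {self.operating_theta}")

    def fit(self, X, y):
        self._validate_params_values()
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        Xa = _as_array(X)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("y contains a single class; cannot fit cascade")
        if not set(self.classes_) <= {0, 1}:
            raise ValueError(f"labels must be binary 0/1, got {self.classes_}")
        self.n_features_in_ = Xa.shape[1]
        trees = []
        for cost in (self.c_low, self.c_high):
            clf = DecisionTreeClassifier(
                max_depth=self.max_depth,
                class_weight={0: 1.0, 1: float(cost)},
                random_state=self.random_state,
            ).fit(Xa, y)
            trees.append(_Tree.from_sklearn(clf, self.classes_))
        self.stage1_tree_, self.stage2_tree_ = trees
        return self

    def predict_detail(self, X):
        """Labels, deciding-stage positive-class probability, and stage.

        Returns ``(labels, probs, stages)`` arrays.  Stage 1 decides when
        its predicted-class leaf probability strictly exceeds tau; deferred
        samples are decided by stage 2 at theta (positive iff prob >= theta).
        """
        check_is_fitted(self, "stage1_tree_")
        Xa = _as_array(X, getattr(self, "feature_names_in_", None))
        if Xa.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {Xa.shape[1]} features, expected {self.n_features_in_}"
            )
        p1 = self.stage1_tree_.predict_pos_prob(Xa)
        conf1 = np.maximum(p1, 1.0 - p1)
        accept = conf1 > self.reliability_tau
        labels = np.where(p1 >= 0.5, 1, 0)
        probs = p1.copy()
        stages = np.ones(Xa.shape[0], dtype=int)
        if (~accept).any():
            p2 = self.stage2_tree_.predict_pos_prob(Xa[~accept])
            labels[~accept] = (p2 >= self.operating_theta).astype(int)
            probs[~accept] = p2
            stages[~accept] = 2
        return labels, probs, stages

    def predict(self, X):
        return self.predict_detail(X)[0]

    def predict_proba(self, X):
        """Positive-class probability of the deciding stage, as (n, 2)."""
        p = self.predict_detail(X)[1]
        return np.column_stack([1.0 - p, p])

    def decision_scores(self, X) -> np.ndarray:
        """Positive-class probability of the deciding stage (for ROC/AUC)."""
        return self.predict_detail(X)[1]

    def tune_operating_point(self, X_val, y_val) -> float:
        """Set theta from the stage-2 ROC on validation data.

        Candidate thresholds are midpoints between consecutive distinct
        stage-2 scores; the candidate maximizing Youden's J is chosen, ties
        resolving to the smaller theta (favoring sensitivity).  Returns the
        tuned theta (also stored in ``operating_theta``).  A single-class
        validation set keeps the default 0.5 with a warning.
        """
        check_is_fitted(self, "stage2_tree_")
        theta = tune_operating_point(
            self.stage2_tree_.predict_pos_prob(
                _as_array(X_val, getattr(self, "feature_names_in_", None))
            ),
            y_val,
        )
        self.operating_theta = theta
        return theta

    def split_feature_names(self) -> set:
        """Names (or indices) of features used in any split of either tree."""
        check_is_fitted(self, "stage1_tree_")
        idx = self.stage1_tree_.split_features() | self.stage2_tree_.split_features()
        names = getattr(self, "feature_names_in_", None)
        return {names[i] for i in idx} if names is not None else idx

    def to_json(self) -> str:
        check_is_fitted(self, "stage1_tree_")
        payload = {
            "params": self.get_params(),
            "classes": self.classes_.tolist(),
            "n_features_in": int(self.n_features_in_),
            "feature_names_in": (
                list(self.feature_names_in_)
                if getattr(self, "feature_names_in_", None) is not None
                else None
            ),
            "stage1": self.stage1_tree_.to_dict(),
            "stage2": self.stage2_tree_.to_dict(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "CascadeDecisionTreeClassifier":
        payload = json.loads(text)
        model = cls(**payload["params"])
        model.classes_ = np.asarray(payload["classes"])
        model.n_features_in_ = payload["n_features_in"]
        if payload["feature_names_in"] is not None:
            model.feature_names_in_ = np.asarray(
                payload["feature_names_in"], dtype=object
            )
        model.stage1_tree_ = _Tree.from_dict(payload["stage1"])
        model.stage2_tree_ = _Tree.from_dict(payload["stage2"])
        return model


def tune_operating_point(scores, y_val) -> float:
    """Youden-optimal threshold over midpoints of consecutive distinct scores.

    Ties go to the smaller threshold; degenerate inputs (single class or a
    single distinct score) return 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    y_val = np.asarray(y_val, dtype=int)
    if np.unique(y_val).size < 2:
        warnings.warn(
            "single-class validation set; keeping default operating point 0.5",
            stacklevel=2,
        )
        return 0.5
    distinct = np.unique(scores)
    if distinct.size < 2:
        return 0.5
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    n_pos = (y_val == 1).sum()
    n_neg = (y_val == 0).sum()
    best_theta, best_j = 0.5, -np.inf
    for theta in candidates:
        pred = scores >= theta
        sens = (pred & (y_val == 1)).sum() / n_pos
        spec = (~pred & (y_val == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j:  # strict: ties keep the smaller (earlier) theta
            best_theta, best_j = float(theta), j
    return best_theta
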
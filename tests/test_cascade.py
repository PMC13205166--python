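"""Two-level cost-sensitive decision-tree cascade: training, routing,
operating-point tuning and serialization."""

import numpy as np
import pandas as pd
import pytest

from petct_radiomics.cascade import CascadeDecisionTreeClassifier, tune_operating_point


def _separable(n=20, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = np.column_stack([y * 10 + rng.normal(0, 0.5, n), rng.random(n)])
    return X, y


def _noisy(n=40, seed=1):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = np.column_stack([y + rng.normal(0, 1.2, n), rng.random(n)])
    return X, y


class TestTraining:
    def test_equal_costs_degenerate_to_single_tree(self):
        X, y = _noisy()
        cascade = CascadeDecisionTreeClassifier(c_low=2, c_high=2).fit(X, y)
        single = CascadeDecisionTreeClassifier(
            c_low=2, c_high=2, reliability_tau=0.0
        ).fit(X, y)
        np.testing.assert_array_equal(cascade.predict(X), single.predict(X))
        np.testing.assert_array_equal(
            cascade.stage1_tree_.pos_prob, cascade.stage2_tree_.pos_prob
        )

    def test_separable_data_perfect_on_both_stages(self):
        X, y = _separable()
        clf = CascadeDecisionTreeClassifier().fit(X, y)
        assert (clf.stage1_tree_.predict_pos_prob(X.astype(float)) >= 0.5).astype(
            int
        ).tolist() == y.tolist()
        assert (clf.stage2_tree_.predict_pos_prob(X.astype(float)) >= 0.5).astype(
            int
        ).tolist() == y.tolist()
        assert (clf.predict(X) == y).all()

    def test_single_class_raises(self):
        X = np.zeros((6, 2))
        with pytest.raises(ValueError, match="single class"):
            CascadeDecisionTreeClassifier().fit(X, np.zeros(6, dtype=int))

    def test_higher_fn_cost_never_lowers_stage2_sensitivity(self):
        """On a fixed 12-row toy, the weighted-gini stump oracle and the
        fitted stage-2 stump agree, and sensitivity rises with the FN cost."""
        x = np.arange(12, dtype=float)
        y = np.array([0, 1, 0, 0, 0, 1, 0, 0, 1, 1, 0, 1])

        def oracle_stump_sensitivity(cost):
            w = np.where(y == 1, cost, 1.0)
            best_thr, best_imp = None, np.inf
            for thr in (np.arange(11) + 0.5):
                imp = 0.0
                for sel in (x <= thr, x > thr):
                    ww = w[sel].sum()
                    if ww:
                        p1 = w[sel & (y == 1)].sum() / ww
                        imp += 2 * p1 * (1 - p1) * ww
                if imp < best_imp - 1e-12:
                    best_thr, best_imp = thr, imp
            pred = np.empty_like(y)
            for sel in (x <= best_thr, x > best_thr):
                pred[sel] = int(
                    w[sel & (y == 1)].sum() >= w[sel & (y == 0)].sum()
                )
            return pred[y == 1].mean()

        ours, oracle = [], []
        for cost in (1, 2, 3, 5, 8):
            clf = CascadeDecisionTreeClassifier(
                c_low=1, c_high=cost, max_depth=1, reliability_tau=1.0
            ).fit(x.reshape(-1, 1), y)
            ours.append(clf.predict(x.reshape(-1, 1))[y == 1].mean())
            oracle.append(oracle_stump_sensitivity(cost))
        assert ours == oracle
        assert all(a <= b for a, b in zip(ours, ours[1:]))


class TestRouting:
    def test_confident_stage1_decides(self):
        X, y = _separable()
        clf = CascadeDecisionTreeClassifier().fit(X, y)
        labels, probs, stages = clf.predict_detail(X)
        assert (stages == 1).all()  # pure leaves: confidence 1.0 > 0.5

    def test_balanced_leaf_routes_to_stage2(self):
        # one feature value shared by both classes -> stage-1 leaf prob 0.5
        X = np.array([[0.0], [0.0], [5.0], [5.0]])
        y = np.array([0, 1, 0, 1])
        clf = CascadeDecisionTreeClassifier(c_low=1, c_high=1, max_depth=2).fit(X, y)
        _, _, stages = clf.predict_detail(X)
        assert (stages == 2).all()

    def test_theta_zero_predicts_positive_for_routed(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0]])
        y = np.array([0, 1, 0, 1])
        clf = CascadeDecisionTreeClassifier(
            c_low=1, c_high=1, max_depth=2, operating_theta=0.0
        ).fit(X, y)
        assert clf.predict(X).tolist() == [1, 1, 1, 1]

    def test_tau_limits_reduce_to_single_stages(self):
        X, y = _noisy()
        base = CascadeDecisionTreeClassifier(c_low=1, c_high=4, max_depth=3)
        low_only = base.set_params(reliability_tau=0.0).fit(X, y)
        labels, probs, stages = low_only.predict_detail(X)
        assert (stages == 1).all()
        np.testing.assert_array_equal(
            labels, (low_only.stage1_tree_.predict_pos_prob(X) >= 0.5).astype(int)
        )
        high_only = CascadeDecisionTreeClassifier(
            c_low=1, c_high=4, max_depth=3, reliability_tau=1.0, operating_theta=0.3
        ).fit(X, y)
        labels2, _, stages2 = high_only.predict_detail(X)
        assert (stages2 == 2).all()
        np.testing.assert_array_equal(
            labels2, (high_only.stage2_tree_.predict_pos_prob(X) >= 0.3).astype(int)
        )

    def test_positives_nonincreasing_in_theta(self):
        X, y = _noisy()
        clf = CascadeDecisionTreeClassifier(reliability_tau=1.0).fit(X, y)
        counts = []
        for theta in np.linspace(0, 1, 11):
            clf.operating_theta = theta
            counts.append(int(clf.predict(X).sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_deterministic_predictions(self):
        X, y = _noisy()
        clf = CascadeDecisionTreeClassifier().fit(X, y)
        np.testing.assert_array_equal(clf.predict(X), clf.predict(X))

    def test_missing_feature_named(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 0.0, 1.0], "b": [1.0, 0.0, 1.0, 0.0]})
        clf = CascadeDecisionTreeClassifier().fit(X, [0, 1, 0, 1])
        with pytest.raises(ValueError, match="'b'"):
            clf.predict(X[["a"]])


class TestTuneOperatingPoint:
    def test_exhaustive_sweep_example(self):
        # midpoints of {.1,.35,.4,.8} are {.225,.375,.6}; J = .5, 0, .5 ->
        # tie resolved to the smaller theta
        theta = tune_operating_point([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert theta == pytest.approx(0.225)

    def test_separable_scores(self):
        theta = tune_operating_point([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert 0.2 < theta < 0.8

    def test_identical_scores_default(self):
        assert tune_operating_point([0.4] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_single_class_warns_and_defaults(self):
        with pytest.warns(UserWarning, match="single-class"):
            assert tune_operating_point([0.1, 0.9], [1, 1]) == 0.5

    def test_method_sets_theta(self):
        X, y = _separable()
        clf = CascadeDecisionTreeClassifier().fit(X, y)
        theta = clf.tune_operating_point(X, y)
        assert clf.operating_theta == theta
        assert 0.0 <= theta <= 1.0


class TestSerialization:
    def test_json_round_trip_bit_exact(self, rng):
        X, y = _noisy(seed=7)
        clf = CascadeDecisionTreeClassifier(c_low=1, c_high=3, max_depth=4).fit(X, y)
        clf.operating_theta = 0.37
        restored = CascadeDecisionTreeClassifier.from_json(clf.to_json())
        Xnew = rng.normal(size=(50, 2)) * 3
        for a, b in zip(clf.predict_detail(Xnew), restored.predict_detail(Xnew)):
            np.testing.assert_array_equal(a, b)

    def test_round_trip_preserves_params(self):
        X, y = _noisy()
        clf = CascadeDecisionTreeClassifier(c_low=1, c_high=5, max_depth=2).fit(X, y)
        restored = CascadeDecisionTreeClassifier.from_json(clf.to_json())
        assert restored.get_params() == clf.get_params()

    def test_split_feature_names(self):
        X = pd.DataFrame(
            {"informative": [0.0, 0.0, 1.0, 1.0] * 5, "junk": [0.5] * 20}
        )
        y = np.array([0, 0, 1, 1] * 5)
        clf = CascadeDecisionTreeClassifier().fit(X, y)
        assert clf.split_feature_names() == {"informative"}
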
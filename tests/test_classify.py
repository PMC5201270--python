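"""Classification contracts: logistic IRLS, ROC/AUC, DeLong, trees."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ecgrepol import classify as cl


def _labels(y01):
    return np.where(np.asarray(y01) == 1, cl.POSITIVE_CLASS, cl.NEGATIVE_CLASS)


def brute_force_auc(scores, y01):
    """All-pairs Mann-Whitney statistic (ties count one half)."""
    pos = [s for s, y in zip(scores, y01) if y == 1]
    neg = [s for s, y in zip(scores, y01) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestLogistic:
    def test_separated_toy_warns_and_scores_correctly(self):
        x = np.array([-3, -2.5, -2, -1.5, -1, 1, 1.5, 2, 2.5, 3.0])[:, None]
        y = _labels([0] * 5 + [1] * 5)
        with pytest.warns(RuntimeWarning, match="separation"):
            m = cl.logistic_fit(x, y)
        proba = m.predict_proba(x)
        assert np.all(proba[:5] < 0.5) and np.all(proba[5:] > 0.5)

    def test_null_association_gives_flat_probabilities(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 400)[:, None]
        y01 = np.tile([0, 1], 200)
        m = cl.logistic_fit(x, _labels(y01))
        assert abs(m.coef[1]) < 0.2
        assert np.mean(m.predict_proba(x)) == pytest.approx(0.5, abs=0.02)

    def test_coefficients_match_grid_search_oracle(self):
        """8-row toy: IRLS maximum matches a brute-force likelihood grid."""
        x = np.array([0.2, 0.8, 1.1, 1.9, 2.4, 3.0, 3.3, 4.1])
        y01 = np.array([0, 0, 1, 0, 1, 1, 0, 1])
        m = cl.logistic_fit(x[:, None], _labels(y01))

        def nll(b0, b1):
            z = b0 + b1 * x
            return float(np.sum(np.log1p(np.exp(z))) - np.sum(y01 * z))

        b0s = np.linspace(m.coef[0] - 0.5, m.coef[0] + 0.5, 201)
        b1s = np.linspace(m.coef[1] - 0.5, m.coef[1] + 0.5, 201)
        grid = np.array([[nll(a, b) for b in b1s] for a in b0s])
        i, j = np.unravel_index(np.argmin(grid), grid.shape)
        assert abs(b0s[i] - m.coef[0]) < 1e-2 and abs(b1s[j] - m.coef[1]) < 1e-2

    def test_matches_sklearn_unpenalized(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (120, 2))
        y01 = (rng.random(120) < 1 / (1 + np.exp(-(0.5 + X @ [1.0, -0.7])))).astype(int)
        m = cl.logistic_fit(X, _labels(y01))
        sk = sklearn.LogisticRegression(penalty=None, max_iter=500).fit(X, y01)
        assert m.coef[0] == pytest.approx(sk.intercept_[0], abs=1e-4)
        np.testing.assert_allclose(m.coef[1:], sk.coef_[0], atol=1e-4)


class TestRocAuc:
    def test_perfect_separation(self):
        r = cl.roc_auc([1, 2, 3, 11, 12, 13], _labels([0, 0, 0, 1, 1, 1]))
        assert r.auc == 1.0 and r.best_sensitivity == 1.0 and r.best_specificity == 1.0

    def test_label_flip_antisymmetry(self):
        rng = np.random.default_rng(5)
        s = rng.normal(0, 1, 40)
        y01 = rng.integers(0, 2, 40)
        y01[0], y01[1] = 0, 1
        a = cl.roc_auc(s, _labels(y01)).auc
        b = cl.roc_auc(s, _labels(1 - y01)).auc
        assert a == pytest.approx(1 - b, abs=1e-12)

    def test_tied_toy_matches_pair_enumeration(self):
        s = [0.1, 0.4, 0.4, 0.7, 0.9, 0.9]
        y01 = [0, 0, 1, 0, 1, 1]
        assert cl.roc_auc(s, _labels(y01)).auc == pytest.approx(
            brute_force_auc(s, y01), abs=1e-12
        )

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            cl.roc_auc([1, 2, 3], [cl.POSITIVE_CLASS] * 3)

    @given(st.data())
    def test_monotone_transform_invariance(self, data):
        n = data.draw(st.integers(6, 24))
        scores = np.round(
            np.array(data.draw(st.lists(st.floats(-5, 5), min_size=n, max_size=n))), 3
        )
        y01 = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        if y01.min() == y01.max():
            y01[0], y01[-1] = 0, 1
        a = cl.roc_auc(scores, _labels(y01)).auc
        b = cl.roc_auc(np.exp(0.5 * scores), _labels(y01)).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestBootstrapCi:
    def test_degenerate_scores_give_half_interval(self):
        ci = cl.auc_bootstrap_ci(np.ones(20), _labels([0, 1] * 10), 200, seed=0)
        assert ci == (0.5, 0.5)

    def test_same_seed_same_interval(self):
        rng = np.random.default_rng(9)
        s = rng.normal(0, 1, 30)
        y = _labels(rng.integers(0, 2, 30))
        assert cl.auc_bootstrap_ci(s, y, 500, seed=4) == cl.auc_bootstrap_ci(s, y, 500, seed=4)

    def test_small_n_boot_warns(self):
        with pytest.warns(RuntimeWarning):
            cl.auc_bootstrap_ci(np.arange(10.0), _labels([0, 1] * 5), 50, seed=0)


class TestDeLong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(2)
        s = rng.normal(0, 1, 30)
        y = _labels(rng.integers(0, 2, 30))
        res = cl.delong_test(s, s, y)
        assert res["p_value"] == 1.0

    def test_monotone_transform_p_one(self):
        rng = np.random.default_rng(2)
        s = rng.normal(0, 1, 30)
        y = _labels(rng.integers(0, 2, 30))
        res = cl.delong_test(s, np.tanh(s), y)
        assert res["auc_a"] == pytest.approx(res["auc_b"], abs=1e-12)
        assert res["p_value"] == 1.0

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            cl.delong_test(np.arange(10.0), np.arange(9.0), _labels([0, 1] * 5))


class TestTreeRule:
    def test_published_mean_changes_classify_correctly(self):
        """The reported placebo-corrected (ddJ-Tpeakc, ddQTc) means: the
        hERG blocker alone lands hERG, both combinations multichannel."""
        assert cl.tree_classify(29.1, 45.2) == "hERG"
        assert cl.tree_classify(1.1, 17.3) == "multichannel"
        assert cl.tree_classify(4.1, 17.9) == "multichannel"

    def test_boundary_uses_inclusive_lower_branch(self):
        assert cl.tree_classify(9.0, 29.0) == "multichannel"
        assert cl.tree_classify(5.0, 35.0) == "inconclusive"
        assert cl.tree_classify(9.0001, 35.0) == "hERG"

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            cl.tree_classify(np.nan, 10.0)

    @given(
        st.floats(-100, 100, allow_nan=False),
        st.floats(-100, 100, allow_nan=False),
    )
    def test_partition_is_exhaustive_and_disjoint(self, jt, qt):
        out = cl.tree_classify(jt, qt)
        assert out in {"hERG", "multichannel", "inconclusive"}
        # region membership is mutually exclusive by definition of the rule
        in_herg = jt > 9.0
        in_multi = jt <= 9.0 and qt <= 29.0
        in_inc = jt <= 9.0 and qt > 29.0
        assert [in_herg, in_multi, in_inc].count(True) == 1
        expected = "hERG" if in_herg else ("multichannel" if in_multi else "inconclusive")
        assert out == expected


class TestLearnTree:
    def test_separated_clusters_split_in_the_gap(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [
                np.c_[rng.normal(-3, 0.5, 40), rng.normal(0, 1, 40)],
                np.c_[rng.normal(3, 0.5, 40), rng.normal(0, 1, 40)],
            ]
        )
        y = _labels([1] * 40 + [0] * 40)
        tree = cl.learn_tree(X, y, seed=1)
        assert tree.root.feature == 0
        assert -2 < tree.root.threshold < 2
        assert tree.cv_metrics["accuracy"] > 0.95

    def test_uninformative_features_give_prevalence_accuracy(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (120, 2))
        y = _labels(np.r_[np.ones(72, int), np.zeros(48, int)])
        tree = cl.learn_tree(X, y, seed=2)
        assert abs(tree.cv_metrics["accuracy"] - 0.6) < 0.15

    def test_gain_ratio_matches_hand_computed_entropy(self):
        """8-row toy split 6|2 with known class counts."""
        values = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        y = np.array([0, 0, 0, 1, 0, 1, 1, 1])
        thr = 6.5
        # left: {1..6}: 4 zeros 2 ones; right: {7,8}: 2 ones
        h = lambda p: -sum(q * np.log2(q) for q in p if q > 0)
        parent = h([0.5, 0.5])
        child = 6 / 8 * h([4 / 6, 2 / 6]) + 2 / 8 * h([1.0])
        expected = (parent - child) / h([6 / 8, 2 / 8])
        assert cl.gain_ratio(values, y, thr) == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cl.learn_tree(np.random.default_rng(0).normal(0, 1, (30, 2)),
                          [cl.POSITIVE_CLASS] * 30)


class TestEvaluate:
    def test_all_correct(self):
        y = _labels([0, 1, 1, 0])
        assert cl.evaluate_classifier(y, y, n_boot=0)["accuracy"] == 1.0

    def test_all_inconclusive_scores_zero(self):
        y = _labels([0, 1, 1, 0])
        preds = np.array(["inconclusive"] * 4, dtype=object)
        assert cl.evaluate_classifier(preds, y, n_boot=0)["accuracy"] == 0.0

    def test_2x2_table_arithmetic(self):
        y = _labels([1] * 20 + [0] * 20)
        preds = _labels([1] * 15 + [0] * 5 + [1] * 5 + [0] * 15)
        out = cl.evaluate_classifier(preds, y, n_boot=0)
        assert out["accuracy"] == 0.75
        assert out["sensitivity"] == 0.75
        assert out["specificity"] == 0.75

    def test_exclude_inconclusive_recomputes_on_conclusive_rows(self):
        y = _labels([1, 1, 0, 0])
        preds = np.array(
            [cl.POSITIVE_CLASS, "inconclusive", cl.NEGATIVE_CLASS, "inconclusive"],
            dtype=object,
        )
        full = cl.evaluate_classifier(preds, y, n_boot=0)
        part = cl.evaluate_classifier(preds, y, n_boot=0, exclude_inconclusive=True)
        assert full["accuracy"] == 0.5 and part["accuracy"] == 1.0
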
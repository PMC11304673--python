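"""Shapley attributions: exactness, additivity, pooling, rankings, directionality."""

from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from cmcpatterns.classify import CVConfig, run_nested_cv
from cmcpatterns.explain import (
    compute_shap_cv,
    directionality_summary,
    forest_shap_values,
    global_importance,
)


def brute_force_shap(tree, x, n_features):
    """Independent oracle: subset enumeration with the path-dependent
    (cover-weighted) conditional expectation."""
    t = tree.tree_

    def cond_exp(S):
        def rec(node):
            if t.children_left[node] < 0:
                v = t.value[node, 0, :]
                return v / v.sum()
            f = t.feature[node]
            left, right = t.children_left[node], t.children_right[node]
            if f in S:
                return rec(left) if x[f] <= t.threshold[node] else rec(right)
            wl = t.weighted_n_node_samples[left]
            wr = t.weighted_n_node_samples[right]
            return (wl * rec(left) + wr * rec(right)) / (wl + wr)

        return rec(0)

    phi = np.zeros((n_features, tree.n_classes_))
    for j in range(n_features):
        others = [f for f in range(n_features) if f != j]
        for k in range(n_features):
            for S in combinations(others, k):
                w = factorial(k) * factorial(n_features - k - 1) / factorial(n_features)
                phi[j] += w * (cond_exp(set(S) | {j}) - cond_exp(set(S)))
    return phi


@pytest.fixture(scope="module")
def fitted_forest():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(400, 6))
    X[:, 5] = 2.5  # constant feature
    y = ((X[:, 0] > 0) & (X[:, 1] + 0.3 * X[:, 2] > 0)).astype(int)
    rf = RandomForestClassifier(n_estimators=60, random_state=0).fit(X, y)
    return rf, X


class TestForestShap:
    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] + X[:, 1] * X[:, 2] > 0).astype(int)
        rf = RandomForestClassifier(n_estimators=4, max_depth=4, random_state=1).fit(X, y)
        phi, base = forest_shap_values(rf, X[:4])
        for i in range(4):
            expected = np.mean(
                [brute_force_shap(est, X[i], 4) for est in rf.estimators_], axis=0
            )
            assert np.allclose(phi[i], expected, atol=1e-12)

    def test_additivity_to_predicted_probability(self, fitted_forest):
        rf, X = fitted_forest
        phi, base = forest_shap_values(rf, X[:100])
        reconstructed = base + phi.sum(axis=1)
        assert np.abs(reconstructed - rf.predict_proba(X[:100])).max() < 1e-6

    def test_constant_feature_zero_attribution(self, fitted_forest):
        rf, X = fitted_forest
        phi, _ = forest_shap_values(rf, X[:50])
        assert np.abs(phi[:, 5, :]).max() == 0.0

    def test_informative_feature_outranks_noise(self, fitted_forest):
        rf, X = fitted_forest
        phi, _ = forest_shap_values(rf, X[:200])
        mean_abs = np.abs(phi[:, :, 1]).mean(axis=0)
        assert mean_abs[0] > mean_abs[3]
        assert mean_abs[1] > mean_abs[4]

    def test_non_tree_model_rejected(self):
        with pytest.raises(TypeError):
            forest_shap_values(object(), np.zeros((1, 2)))


@pytest.fixture(scope="module")
def cv_shap():
    rng = np.random.default_rng(5)
    n = 300
    x = rng.normal(size=n)
    cat = rng.choice(["lo", "hi"], size=n, p=[0.6, 0.4])
    noise = rng.normal(size=n)
    logit = 1.6 * x + 1.2 * (cat == "hi")
    y = np.where(logit + rng.normal(scale=0.6, size=n) > 0.5, "case", "ctrl")
    table = pd.DataFrame({"x": x, "cat": cat, "noise": noise})
    cfg = CVConfig(outer_folds=4, repeats=2, inner_folds=2, seed=2,
                   grid=({"n_estimators": 60, "max_depth": None,
                          "min_samples_leaf": 1},))
    _, folds = run_nested_cv(table, y, cfg)
    return compute_shap_cv(folds), folds


class TestComputeShapCV:
    def test_pool_covers_each_row_once_per_repeat(self, cv_shap):
        result, folds = cv_shap
        reps = folds[-1].repeat + 1
        assert len(result.values) == 300 * reps
        counts = pd.Series(result.row_ids).value_counts()
        assert (counts == reps).all()

    def test_additivity_for_every_pooled_attribution(self, cv_shap):
        result, folds = cv_shap
        pred = result.predicted_probability()
        proba = np.concatenate([f.proba for f in folds])
        assert np.abs(pred - proba).max() < 1e-6

    def test_empty_folds_rejected(self):
        with pytest.raises(ValueError):
            compute_shap_cv([])


class TestGlobalImportance:
    def test_planted_driver_ranks_first(self, cv_shap):
        result, _ = cv_shap
        top = global_importance(result, "case", top_m=3)
        assert top.iloc[0]["feature"] == "x"
        assert "noise" not in set(top["feature"])

    def test_ranks_are_permutation(self, cv_shap):
        result, _ = cv_shap
        full = global_importance(result, "ctrl", top_m=None)
        assert sorted(full["rank"]) == list(range(1, len(result.feature_names) + 1))
        assert (full["mean_abs_shap"] >= 0).all()
        assert full["mean_abs_shap"].is_monotonic_decreasing

    def test_importance_bounded_by_max_row_attribution(self, cv_shap):
        result, _ = cv_shap
        full = global_importance(result, "case", top_m=None)
        c = result.class_index("case")
        for _, row in full.iterrows():
            j = result.feature_names.index(row["feature"])
            assert row["mean_abs_shap"] <= np.abs(result.values[:, j, c]).max() + 1e-15

    def test_level_aggregation_sums_indicators(self, cv_shap):
        result, _ = cv_shap
        agg = global_importance(result, "case", top_m=None, aggregate_levels=True)
        assert "cat" in set(agg["feature"])
        assert not any(f.startswith("cat.") for f in agg["feature"])

    def test_stable_order_for_all_zero_attributions(self, cv_shap):
        result, _ = cv_shap
        zeroed = type(result)(
            values=np.zeros_like(result.values),
            base_values=result.base_values,
            feature_values=result.feature_values,
            row_ids=result.row_ids, repeat=result.repeat, fold=result.fold,
            feature_names=result.feature_names, classes=result.classes,
        )
        full = global_importance(zeroed, "case", top_m=None)
        assert full["feature"].tolist() == result.feature_names
        assert (full["mean_abs_shap"] == 0).all()


class TestDirectionality:
    def test_monotone_effect_concordant(self, cv_shap):
        result, _ = cv_shap
        _, score = directionality_summary(result, "x", "case")
        assert score > 0.5

    def test_indicator_level_positive_share(self, cv_shap):
        result, _ = cv_shap
        table, score = directionality_summary(result, "cat.hi", "case")
        assert score > 0.5
        assert set(np.unique(table["value"])) <= {0.0, 1.0}

    def test_constant_feature_undefined(self, cv_shap):
        result, _ = cv_shap
        const = type(result)(
            values=result.values,
            base_values=result.base_values,
            feature_values=np.full_like(result.feature_values, 3.0),
            row_ids=result.row_ids, repeat=result.repeat, fold=result.fold,
            feature_names=result.feature_names, classes=result.classes,
        )
        _, score = directionality_summary(const, "x", "case")
        assert np.isnan(score)

    def test_flipped_effect_flips_attribution_sign(self):
        """Reversing a planted monotone effect reverses the mean attribution
        among high feature values."""
        means = []
        for sign in (+1.0, -1.0):
            rng = np.random.default_rng(17)
            x = rng.normal(size=250)
            y = np.where(sign * x + rng.normal(scale=0.5, size=250) > 0, "case", "ctrl")
            rf = RandomForestClassifier(n_estimators=60, random_state=0).fit(
                x[:, None], y
            )
            phi, _ = forest_shap_values(rf, x[:, None])
            c = list(rf.classes_).index("case")
            means.append(phi[x > 0.5, 0, c].mean())
        assert means[0] > 0 > means[1]

    def test_unknown_feature_rejected(self, cv_shap):
        result, _ = cv_shap
        with pytest.raises(KeyError):
            directionality_summary(result, "nope", "case")
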
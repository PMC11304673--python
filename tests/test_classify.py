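"""Preprocessing, SMOTE, weighted metrics and leakage-controlled nested CV."""

import numpy as np
import pandas as pd
import pytest

from cmcpatterns.classify import (
    CVConfig,
    leaky_cv_smote_before_split,
    preprocess_apply,
    preprocess_fit,
    run_nested_cv,
    smote_balance,
    weighted_metrics,
)


class TestPreprocessor:
    def test_median_imputation_by_hand(self):
        train = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 100.0]})
        pre = preprocess_fit(train)
        test = pd.DataFrame({"x": [np.nan]})
        out = preprocess_apply(pre, test)
        # imputed with the train median 3, then standardised by train stats
        assert out[0, 0] == pytest.approx((3.0 - train["x"].mean()) / train["x"].std(ddof=0))

    def test_constant_feature_maps_to_zeros(self):
        train = pd.DataFrame({"x": [5.0, 5.0, 5.0], "y": [1.0, 2.0, 3.0]})
        pre = preprocess_fit(train)
        out = preprocess_apply(pre, train)
        assert np.allclose(out[:, 0], 0.0)
        assert not np.allclose(out[:, 1], 0.0)

    def test_unseen_test_level_gives_zero_block(self):
        train = pd.DataFrame({"c": ["a", "b", "a", "b"]})
        pre = preprocess_fit(train)
        out = preprocess_apply(pre, pd.DataFrame({"c": ["z"]}))
        assert out.shape == (1, 2)
        assert np.allclose(out, 0.0)

    def test_categorical_mode_imputation(self):
        train = pd.DataFrame({"c": ["a", "a", "b", None]})
        pre = preprocess_fit(train)
        out = preprocess_apply(pre, pd.DataFrame({"c": [None]}))
        # missing -> mode "a" -> indicator (1, 0)
        assert out.tolist() == [[1.0, 0.0]]

    def test_all_missing_column_named_in_error(self):
        train = pd.DataFrame({"fine": [1.0, 2.0], "broken": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="broken"):
            preprocess_fit(train)

    def test_feature_names_cover_matrix(self, small_cohort):
        cov, _, _ = small_cohort
        pred = cov.drop(columns=["participant_id", "sex", "follow_up_years"])
        pre = preprocess_fit(pred)
        out = preprocess_apply(pre, pred)
        assert out.shape == (len(pred), len(pre.feature_names_))
        assert np.isfinite(out).all()


class TestSmote:
    def test_balanced_input_unchanged(self, rng):
        X = rng.random((40, 3))
        y = np.repeat(["a", "b"], 20)
        Xb, yb = smote_balance(X, y, seed=0)
        assert len(Xb) == 40
        assert np.array_equal(Xb, X)

    def test_minority_upsampled_to_majority(self, rng):
        X = rng.random((110, 3))
        y = np.array(["maj"] * 100 + ["min"] * 10)
        Xb, yb = smote_balance(X, y, seed=0)
        counts = pd.Series(yb).value_counts()
        assert counts["maj"] == 100 and counts["min"] == 100

    def test_synthetic_points_on_segment(self, rng):
        """Minority samples on a 1-d line: every synthetic point stays on it."""
        t = np.linspace(0, 1, 8)
        direction = np.array([1.0, 2.0, -1.0])
        X_min = np.outer(t, direction)
        X_maj = rng.random((50, 3)) + 10
        X = np.vstack([X_maj, X_min])
        y = np.array(["maj"] * 50 + ["min"] * 8)
        Xb, yb = smote_balance(X, y, k_neighbors=3, seed=1)
        synth = Xb[58:]
        assert (yb[58:] == "min").all()
        # collinearity with the generating direction
        cross = np.cross(synth, direction)
        assert np.allclose(cross, 0.0, atol=1e-9)

    def test_singleton_class_skipped_with_warning(self, rng):
        X = rng.random((11, 2))
        y = np.array(["a"] * 10 + ["b"])
        with pytest.warns(UserWarning, match="single member"):
            Xb, yb = smote_balance(X, y, seed=0)
        assert (yb == "b").sum() == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            smote_balance(np.empty((0, 2)), np.array([]))


class TestWeightedMetrics:
    def test_perfect_predictions(self):
        y = ["a", "b", "c", "a"]
        m = weighted_metrics(y, y)
        assert all(v == pytest.approx(1.0) for v in m.values())

    def test_hand_computed_three_class_confusion(self):
        """Confusion rows (5,1,0 / 0,4,2 / 1,0,7) against hand arithmetic."""
        y_true = [0] * 6 + [1] * 6 + [2] * 8
        y_pred = [0] * 5 + [1] + [1] * 4 + [2] * 2 + [0] + [2] * 7
        m = weighted_metrics(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(16 / 20)
        assert m["recall"] == pytest.approx(16 / 20)
        assert m["precision"] == pytest.approx(721 / 900)
        f1 = (6 * (5 / 6) + 6 * (8 / 11) + 8 * (14 / 17)) / 20
        assert m["f1"] == pytest.approx(f1)

    def test_single_class_predictions_on_balanced_truth(self):
        with pytest.warns(UserWarning, match="never predicted"):
            m = weighted_metrics(["a"] * 5 + ["b"] * 5, ["a"] * 10)
        assert m["accuracy"] == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            weighted_metrics([], [])


def separable_table(n, rng, n_classes=3):
    """Labels are a deterministic function of one covariate."""
    x = rng.random(n)
    other = rng.normal(size=n)
    cat = rng.choice(["u", "v"], size=n)
    y = np.digitize(x, np.linspace(0, 1, n_classes + 1)[1:-1])
    table = pd.DataFrame({"x": x, "noise": other, "cat": cat})
    return table, np.char.add("c", y.astype(str))


class TestNestedCV:
    CFG = CVConfig(outer_folds=5, repeats=1, inner_folds=3, seed=7,
                   grid=({"n_estimators": 100, "max_depth": None, "min_samples_leaf": 1},))

    def test_separable_data_high_accuracy(self, rng):
        table, y = separable_table(600, rng)
        metrics, folds = run_nested_cv(table, y, self.CFG)
        assert metrics.mean["accuracy"] >= 0.95

    def test_test_partitions_disjoint_cover(self, rng):
        table, y = separable_table(200, rng)
        _, folds = run_nested_cv(table, y, self.CFG)
        seen = np.concatenate([f.test_ids for f in folds])
        assert sorted(seen) == list(range(200))
        for f in folds:
            assert not set(f.test_ids) & set(f.train_ids)

    def test_same_seed_identical_metrics(self, rng):
        table, y = separable_table(150, rng)
        m1, _ = run_nested_cv(table, y, self.CFG)
        m2, _ = run_nested_cv(table, y, self.CFG)
        assert m1.mean == m2.mean and m1.sd == m2.sd

    def test_row_order_invariance(self, rng):
        table, y = separable_table(150, rng)
        m1, _ = run_nested_cv(table, y, self.CFG)
        perm = rng.permutation(150)
        m2, _ = run_nested_cv(table.iloc[perm].reset_index(drop=True), y[perm], self.CFG)
        for k in m1.mean:
            assert m1.mean[k] == pytest.approx(m2.mean[k], abs=1e-12)

    def test_rare_class_merged_for_splitting_with_warning(self, rng):
        table, y = separable_table(120, rng)
        y = y.copy()
        y[:3] = "rare"
        with pytest.warns(UserWarning, match="fewer than"):
            metrics, folds = run_nested_cv(table, y, self.CFG)
        pooled = np.concatenate([f.y_true for f in folds])
        assert (pooled == "rare").sum() == 3  # true labels kept for scoring

    def test_metrics_within_unit_interval(self, rng):
        table, y = separable_table(150, rng)
        metrics, _ = run_nested_cv(table, y, self.CFG)
        for d in (metrics.mean, metrics.sd):
            for v in d.values():
                assert 0.0 <= v <= 1.0


class TestLeakageControl:
    def test_presplit_smote_is_optimistic(self, rng):
        """SMOTE before splitting leaks held-out minority information and
        inflates metrics on imbalanced, uninformative data."""
        n = 600
        X = rng.normal(size=(n, 3))
        y = np.array(["ctrl"] * n)
        y[rng.choice(n, 30, replace=False)] = "case"
        table = pd.DataFrame(X, columns=["f0", "f1", "f2"])
        cfg = CVConfig(outer_folds=5, repeats=2, inner_folds=3, seed=3,
                       grid=({"n_estimators": 100, "max_depth": None,
                              "min_samples_leaf": 1},))
        correct, _ = run_nested_cv(table, y, cfg)
        leaky = leaky_cv_smote_before_split(table, y, cfg)
        assert leaky.mean["f1"] > correct.mean["f1"]
        assert leaky.mean["accuracy"] > correct.mean["accuracy"]

    def test_fit_never_saw_test_rows(self, rng):
        """The fitted transformer's row count equals the train partition size."""
        table, y = separable_table(150, rng)
        cfg = TestNestedCV.CFG
        _, folds = run_nested_cv(table, y, cfg)
        for f in folds:
            assert f.preprocessor.n_fit_rows_ == len(f.train_ids)
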
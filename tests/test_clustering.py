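"""k-means fitting, silhouette-based k selection, profiling and labeling rules."""

import numpy as np
import pytest

from cmcpatterns.clustering import (
    LOW_SEPARATION_THRESHOLD,
    ClusterModel,
    LabelRuleConfig,
    fit_clusters,
    label_clusters,
    profile_clusters,
    select_k,
)
from cmcpatterns.labels import PatternLabel
from cmcpatterns.trajectory import Trajectory


def make_traj(times, pid="p", fu=10.0):
    occurred = tuple(t < 1.0 for t in times)
    return Trajectory(pid, tuple(times), occurred, fu)


def brute_mean_silhouette(X, assignments):
    """Independent silhouette: direct pairwise-distance definition."""
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    scores = []
    for i in range(n):
        own = assignments == assignments[i]
        if own.sum() == 1:
            scores.append(0.0)
            continue
        a = D[i][own].sum() / (own.sum() - 1)
        b = min(
            D[i][assignments == c].mean()
            for c in np.unique(assignments)
            if c != assignments[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


class TestFitClusters:
    def test_k1_centroid_is_mean(self, rng):
        X = rng.random((20, 4))
        model = fit_clusters(X, 1, seed=0)
        assert np.allclose(model.centroids[0], X.mean(axis=0))
        assert (model.assignments == 0).all()

    def test_k_equals_n_distinct_gives_zero_inertia(self, rng):
        X = rng.random((6, 4))
        model = fit_clusters(X, 6, seed=0)
        assert model.inertia == pytest.approx(0.0, abs=1e-12)

    def test_assignments_are_nearest_centroid(self, small_cohort):
        _, traj, _ = small_cohort
        model = fit_clusters(traj, 5, seed=1)
        from cmcpatterns.trajectory import time_matrix

        X = time_matrix(traj)
        d = ((X[:, None, :] - model.centroids[None, :, :]) ** 2).sum(-1)
        assert (model.assignments == d.argmin(axis=1)).all()

    def test_more_restarts_never_worse(self, small_cohort):
        _, traj, _ = small_cohort
        one = fit_clusters(traj, 5, seed=3, n_init=1)
        many = fit_clusters(traj, 5, seed=3, n_init=10)
        assert many.inertia <= one.inertia + 1e-9

    def test_too_few_distinct_points(self):
        X = np.tile([0.5, 1, 1, 1], (10, 1))
        with pytest.raises(ValueError, match="distinct"):
            fit_clusters(X, 2)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            fit_clusters(np.empty((0, 4)), 1)

    def test_invalid_model_invariants(self):
        with pytest.raises(ValueError):
            ClusterModel(
                k=2, centroids=np.ones((2, 4)), assignments=np.array([0, 2]),
                inertia=0.0, seed=0, n_init=1,
            )


class TestSelectK:
    def test_three_blobs_recovered_and_scores_match_bruteforce(self, rng):
        centers = np.array(
            [[0.1, 1, 1, 1], [0.9, 0.2, 1, 1], [1, 1, 0.5, 0.5]]
        )
        X = np.clip(
            np.repeat(centers, 30, axis=0) + rng.normal(scale=0.03, size=(90, 4)),
            0.01, 1.0,
        )
        k_star, table = select_k(X, range(2, 6), seed=0)
        assert k_star == 3
        for _, row in table.iterrows():
            model = fit_clusters(X, int(row["k"]), seed=0)
            assert row["mean_silhouette"] == pytest.approx(
                brute_mean_silhouette(X, model.assignments), abs=1e-9
            )

    def test_single_blob_warns_low_separation(self, rng):
        X = np.clip(0.5 + rng.normal(scale=0.05, size=(120, 4)), 0.01, 1.0)
        with pytest.warns(UserWarning, match="separation"):
            k_star, table = select_k(X, range(2, 5), seed=0)
        assert table["mean_silhouette"].max() < LOW_SEPARATION_THRESHOLD
        assert k_star == int(table.loc[table["mean_silhouette"].idxmax(), "k"])

    def test_tiny_input_rejected(self):
        with pytest.raises(ValueError):
            select_k(np.ones((2, 4)), [2])

    def test_silhouette_values_within_bounds(self, small_cohort):
        _, traj, _ = small_cohort
        _, table = select_k(traj, range(2, 7), seed=0)
        assert table["mean_silhouette"].between(-1, 1).all()


class TestProfileClusters:
    def test_hand_built_cluster_statistics(self):
        trajs = [
            make_traj((0.2, 0.4, 1.0, 1.0)),
            make_traj((0.4, 1.0, 1.0, 1.0)),
            make_traj((1.0, 1.0, 1.0, 1.0)),
            make_traj((0.6, 1.0, 1.0, 1.0)),
        ]
        model = ClusterModel(
            k=1, centroids=np.zeros((1, 4)), assignments=np.zeros(4, dtype=int),
            inertia=0.0, seed=0, n_init=1,
        )
        (p,) = profile_clusters(model, trajs)
        assert p.n == 4
        assert p.incidence_pct["HYP"] == pytest.approx(75.0)
        assert p.incidence_pct["DM"] == pytest.approx(25.0)
        assert p.mean_time["HYP"] == pytest.approx((0.2 + 0.4 + 0.6) / 3)
        assert p.sd_time["HYP"] == pytest.approx(0.2)
        assert p.mean_time["STK"] is None
        top = p.pattern_counts.iloc[0]
        assert set(p.pattern_counts["pattern"]) == {"HYP→DM", "HYP", "None Disease"}
        assert p.pattern_counts["count"].sum() == 4
        assert top["pattern"] == "HYP"  # two isolated-HYP members
        assert top["pct"] == pytest.approx(50.0)

    def test_all_healthy_cluster(self):
        trajs = [make_traj((1.0, 1.0, 1.0, 1.0)) for _ in range(3)]
        model = ClusterModel(
            k=1, centroids=np.ones((1, 4)), assignments=np.zeros(3, dtype=int),
            inertia=0.0, seed=0, n_init=1,
        )
        (p,) = profile_clusters(model, trajs)
        assert all(v == 0.0 for v in p.incidence_pct.values())
        assert all(v is None for v in p.mean_time.values())
        assert p.none_disease_pct == pytest.approx(100.0)

    def test_half_frequency_pattern(self):
        """A 126-member cluster with 63 DM→HYP trajectories reports 50%."""
        trajs = [make_traj((0.38, 0.35, 1.0, 1.0), pid=str(i)) for i in range(63)]
        trajs += [make_traj((1.0, 0.34, 1.0, 1.0), pid=str(63 + i)) for i in range(63)]
        model = ClusterModel(
            k=1, centroids=np.zeros((1, 4)), assignments=np.zeros(126, dtype=int),
            inertia=0.0, seed=0, n_init=1,
        )
        (p,) = profile_clusters(model, trajs)
        row = p.pattern_counts[p.pattern_counts["pattern"] == "DM→HYP"].iloc[0]
        assert row["count"] == 63
        assert row["pct"] == pytest.approx(50.0)


def one_cluster(trajs):
    model = ClusterModel(
        k=1, centroids=np.zeros((1, 4)), assignments=np.zeros(len(trajs), dtype=int),
        inertia=0.0, seed=0, n_init=1,
    )
    return profile_clusters(model, trajs), model.assignments


class TestLabelClusters:
    def test_early_hyp_rule(self):
        trajs = [make_traj((0.1 + 0.002 * i, 1.0, 1.0, 1.0)) for i in range(96)]
        trajs += [make_traj((0.3, 1.0, 0.2, 1.0)) for _ in range(4)]  # HD first
        profiles, assignments = one_cluster(trajs)
        labels = label_clusters(profiles, trajs, assignments=assignments)
        assert labels[0] == PatternLabel.EARLY_HYP.value

    def test_healthy_rule(self):
        trajs = [make_traj((1.0, 1.0, 1.0, 1.0)) for _ in range(99)]
        trajs += [make_traj((0.9, 1.0, 1.0, 1.0))]
        profiles, assignments = one_cluster(trajs)
        labels = label_clusters(profiles, trajs, assignments=assignments)
        assert labels[0] == PatternLabel.HEALTHY.value

    def test_stroke_only_cluster_unlabeled(self):
        trajs = [make_traj((1.0, 1.0, 1.0, 0.5)) for _ in range(10)]
        profiles, assignments = one_cluster(trajs)
        labels = label_clusters(profiles, trajs, assignments=assignments)
        assert labels[0] == PatternLabel.UNLABELED.value

    def test_late_hyp_window_distinguishes_from_early(self):
        trajs = [make_traj((0.5 + 0.003 * i, 1.0, 1.0, 1.0)) for i in range(100)]
        profiles, assignments = one_cluster(trajs)
        labels = label_clusters(profiles, trajs, assignments=assignments)
        assert labels[0] == PatternLabel.LATE_HYP.value

    def test_duplicate_label_suffixed_with_warning(self):
        trajs = [make_traj((1.0, 1.0, 1.0, 1.0), pid=str(i)) for i in range(20)]
        model = ClusterModel(
            k=2, centroids=np.ones((2, 4)),
            assignments=np.array([0] * 10 + [1] * 10), inertia=0.0, seed=0, n_init=1,
        )
        profiles = profile_clusters(model, trajs)
        with pytest.warns(UserWarning, match="suffix"):
            labels = label_clusters(profiles, trajs, assignments=model.assignments)
        assert sorted(labels.values()) == ["Healthy", "Healthy#2"]

    def test_custom_thresholds(self):
        trajs = [make_traj((1.0, 1.0, 1.0, 1.0)) for _ in range(80)]
        trajs += [make_traj((0.9, 1.0, 1.0, 1.0)) for _ in range(20)]
        profiles, assignments = one_cluster(trajs)
        strict = label_clusters(profiles, trajs, assignments=assignments)
        lax = label_clusters(
            profiles, trajs, assignments=assignments,
            rule_config=LabelRuleConfig(healthy_none_pct=75.0),
        )
        assert strict[0] == PatternLabel.UNLABELED.value
        assert lax[0] == PatternLabel.HEALTHY.value
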
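"""Exact 1-D k-means, thresholds, severity assignment, group distributions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cmskit
from cmskit.clustering import assign_levels, extract_thresholds, kmeans_1d

from conftest import brute_force_kmeans_1d, within_cluster_ss


class TestKmeans1D:
    def test_well_separated_blobs(self):
        x = np.array([0.0, 0.1, 0.2, 5.0, 5.1, 10.0, 10.1])
        centroids, labels = kmeans_1d(x, 3)
        np.testing.assert_allclose(centroids, [0.1, 5.05, 10.05])
        np.testing.assert_array_equal(labels, [0, 0, 0, 1, 1, 2, 2])

    def test_k_equals_n_zero_ss(self):
        x = np.array([3.0, 1.0, 2.0, 5.0])
        _, labels = kmeans_1d(x, 4)
        assert within_cluster_ss(x, labels) == 0.0

    def test_fewer_distinct_values_than_k_errors(self):
        with pytest.raises(ValueError, match="distinct"):
            kmeans_1d([1.0, 1.0, 2.0], 3)

    def test_matches_sklearn_on_separated_data(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(c, 0.3, 40) for c in (-6, 0, 6)])
        centroids, labels = kmeans_1d(x, 3)
        ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit(x.reshape(-1, 1))
        np.testing.assert_allclose(centroids, np.sort(ref.cluster_centers_.ravel()), atol=1e-9)
        assert within_cluster_ss(x, labels) == pytest.approx(ref.inertia_, rel=1e-9)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 100_000),
        n=st.integers(5, 12),
        k=st.sampled_from([2, 3, 4]),
    )
    def test_global_optimum_vs_exhaustive_oracle(self, seed, n, k):
        x = np.random.default_rng(seed).normal(size=n) * 3
        _, labels = kmeans_1d(x, k)
        assert within_cluster_ss(x, labels) == pytest.approx(
            brute_force_kmeans_1d(x, k), abs=1e-9
        )

    def test_partition_contiguous_in_sorted_order(self):
        x = np.random.default_rng(3).normal(size=30)
        _, labels = kmeans_1d(x, 3)
        assert (np.diff(labels[np.argsort(x)]) >= 0).all()


class TestThresholds:
    def test_midpoint_of_outer_values(self):
        x = np.array([0.0, 0.2, 5.0, 5.1, 10.0, 10.1])
        _, labels = kmeans_1d(x, 3)
        thr = extract_thresholds(x, labels)
        np.testing.assert_allclose(thr, [(0.2 + 5.0) / 2, (5.1 + 10.0) / 2])

    def test_touching_clusters_coincident_boundary(self):
        thr = extract_thresholds([0.0, 1.0, 1.0, 9.0], [0, 0, 1, 1])
        np.testing.assert_allclose(thr, [1.0])

    def test_k2_yields_one_threshold(self):
        x = np.array([0.0, 0.1, 8.0, 8.1])
        _, labels = kmeans_1d(x, 2)
        assert extract_thresholds(x, labels).shape == (1,)

    def test_aggregate_identical_runs_zero_width_ci(self):
        ts = cmskit.aggregate_thresholds(np.tile([[1.0, 4.0]], (30, 1)))
        np.testing.assert_allclose(ts.mean, [1.0, 4.0])
        np.testing.assert_allclose(ts.ci_low, ts.ci_high)

    def test_aggregate_percentile_convention(self):
        """Runs 1..100: mean 50.5, linear-interpolation CI [3.475, 97.525]."""
        runs = np.arange(1.0, 101.0).reshape(-1, 1)
        ts = cmskit.aggregate_thresholds(runs)
        assert ts.mean[0] == pytest.approx(50.5)
        assert ts.ci_low[0] == pytest.approx(3.475)
        assert ts.ci_high[0] == pytest.approx(97.525)

    def test_single_run_ci_collapses(self):
        ts = cmskit.aggregate_thresholds([[2.0, 5.0]])
        np.testing.assert_allclose(ts.mean, ts.ci_low)
        np.testing.assert_allclose(ts.mean, ts.ci_high)


class TestAssignLevels:
    def test_published_threshold_interval_map(self):
        """Frozen thresholds (-2.48, 0.70): -3 -> level 3, 0 -> 2, 1 -> 1."""
        levels = assign_levels([-3.0, 0.0, 1.0], [-2.48, 0.70])
        np.testing.assert_array_equal(levels, [3, 2, 1])

    def test_boundary_goes_to_less_severe_side(self):
        assert assign_levels([0.70], [-2.48, 0.70])[0] == 1
        assert assign_levels([-2.48], [-2.48, 0.70])[0] == 2

    def test_all_above_top_threshold(self):
        assert (assign_levels([5.0, 9.0], [-2.48, 0.70]) == 1).all()

    def test_non_increasing_step_function(self):
        x = np.linspace(-6, 6, 201)
        levels = assign_levels(x, [-2.48, 0.70])
        assert (np.diff(levels) <= 0).all()

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            assign_levels([0.0], [1.0, -1.0])


def _scores_from(values, groups=None, models=None):
    idx = pd.Index([f"A{i}" for i in range(len(values))], name="animal_id")
    frame = pd.DataFrame(
        {
            "group": groups if groups is not None else "g",
            "model": models if models is not None else "m",
            "score": np.asarray(values, dtype=float),
            "n_contributing": 4,
            "unreliable": False,
        },
        index=idx,
    )
    return cmskit.CompositeScores(frame=frame, parameters_used=list("abcd"))


class TestRunSeverityClustering:
    def test_planted_blobs_recovered_every_run(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(c, 0.4, 40) for c in (-12, 0, 12)])  # gaps >= 5 SD
        scores = _scores_from(x)
        thresholds, memberships = cmskit.run_severity_clustering(
            scores, cmskit.ClusterConfig(n_runs=50, seed=4)
        )
        expected = np.repeat([3, 2, 1], 40)
        assert (memberships.to_numpy() == expected[:, None]).all()
        assert thresholds.ci_high[0] < -4 and thresholds.ci_low[1] > 4

    def test_single_run_cis_collapse(self):
        x = np.concatenate([[0.0, 0.1], [5.0, 5.1], [10.0, 10.1]])
        thresholds, _ = cmskit.run_severity_clustering(
            _scores_from(x), cmskit.ClusterConfig(n_runs=1, seed=0)
        )
        np.testing.assert_allclose(thresholds.mean, thresholds.ci_low)

    def test_single_blob_wide_cis_flag_instability(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 120)
        tight, _ = cmskit.run_severity_clustering(
            _scores_from(np.concatenate([rng.normal(c, 0.1, 40) for c in (-8, 0, 8)])),
            cmskit.ClusterConfig(n_runs=50, seed=1),
        )
        loose, _ = cmskit.run_severity_clustering(
            _scores_from(x), cmskit.ClusterConfig(n_runs=50, seed=1)
        )
        width = lambda t: (t.ci_high - t.ci_low).mean()
        assert width(loose) > 3 * width(tight)

    def test_threshold_assignment_consistent_with_kmeans_membership(self):
        """Within each run, threshold assignment == k-means labels on training."""
        from cmskit._rng import STAGE_CLUSTER
        from cmskit.selection import ResampleConfig, draw_subsample

        rng = np.random.default_rng(7)
        x = rng.normal(0, 2, 90)
        cfg = cmskit.ClusterConfig(n_runs=25, seed=9)
        _, memberships = cmskit.run_severity_clustering(_scores_from(x), cfg)
        rconf = ResampleConfig(n_runs=cfg.n_runs, train_fraction=cfg.train_fraction,
                               seed=cfg.seed)
        for r in range(cfg.n_runs):
            train, _ = draw_subsample(len(x), rconf, r, stage=STAGE_CLUSTER)
            _, labels = kmeans_1d(x[train], cfg.k)
            severity_from_kmeans = cfg.k - labels
            np.testing.assert_array_equal(
                memberships.iloc[train, r].to_numpy(), severity_from_kmeans
            )

    def test_stability_fraction(self):
        x = np.concatenate([np.full(10, -8.0) + np.arange(10) * 0.01,
                            np.full(10, 8.0) + np.arange(10) * 0.01,
                            [0.0, 0.05, 0.1]])
        thresholds, memberships = cmskit.run_severity_clustering(
            _scores_from(x), cmskit.ClusterConfig(n_runs=40, seed=2)
        )
        assignment = cmskit.assign_severity(_scores_from(x), thresholds, memberships)
        assert ((assignment.frame["stability"] >= 0) & (assignment.frame["stability"] <= 1)).all()
        assert assignment.frame["stability"].iloc[:10].min() == 1.0


class TestGroupDistribution:
    def test_pure_group_is_100_with_zero_sd(self):
        memberships = pd.DataFrame(
            np.full((4, 10), 2), index=pd.Index(list("abcd"), name="animal_id")
        )
        models = pd.Series("m", index=memberships.index)
        groups = pd.Series("g", index=memberships.index)
        dist = cmskit.group_distribution(memberships, models, groups, k=3)
        at2 = dist[dist.severity_level == 2]
        assert at2.mean_pct.iloc[0] == 100.0 and at2.sd_pct.iloc[0] == 0.0

    def test_two_run_arithmetic(self):
        """4-animal group split 50/50 then 75/25 -> mean 62.5%, SD 17.68%."""
        memberships = pd.DataFrame(
            {"run_0": [1, 1, 2, 2], "run_1": [1, 1, 1, 2]},
            index=pd.Index(list("abcd"), name="animal_id"),
        )
        models = pd.Series("m", index=memberships.index)
        groups = pd.Series("g", index=memberships.index)
        dist = cmskit.group_distribution(memberships, models, groups, k=2)
        lvl1 = dist[dist.severity_level == 1].iloc[0]
        assert lvl1.mean_pct == pytest.approx(62.5)
        assert lvl1.sd_pct == pytest.approx(17.6777, abs=1e-3)

    def test_percentages_sum_to_100_every_run(self):
        rng = np.random.default_rng(11)
        n = 30
        memberships = pd.DataFrame(
            rng.integers(1, 4, size=(n, 20)),
            index=pd.Index([f"A{i}" for i in range(n)], name="animal_id"),
        )
        models = pd.Series(rng.choice(["m1", "m2"], n), index=memberships.index)
        groups = pd.Series(rng.choice(["g1", "g2"], n), index=memberships.index)
        dist = cmskit.group_distribution(memberships, models, groups, k=3)
        sums = dist.groupby(["model", "group"])["mean_pct"].sum()
        np.testing.assert_allclose(sums, 100.0, atol=0.1)
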
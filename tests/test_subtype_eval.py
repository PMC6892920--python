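"""Clustering, PCA, Kaplan-Meier and log-rank against oracles."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.metrics import adjusted_rand_score

from mslinc.subtype_eval import (
    dichotomize_by_median,
    hierarchical_cluster,
    km_estimate,
    kmeans_cluster,
    logrank_test,
    pca_project,
    row_center,
)


def blob_matrix(rng, centers, n_per=10, n_features=20, sd=0.3):
    cols, labels = [], []
    for ci, c in enumerate(centers):
        for _ in range(n_per):
            cols.append(rng.normal(c, sd, n_features))
            labels.append(ci)
    m = pd.DataFrame(np.array(cols).T, columns=[f"s{i}" for i in range(len(cols))])
    return m, np.array(labels)


class TestRowCenter:
    def test_simple_row(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["t"])
        assert list(row_center(m).loc["t"]) == [-1.0, 0.0, 1.0]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(5, 7)))
        once = row_center(m)
        pd.testing.assert_frame_equal(once, row_center(once))


class TestHierarchical:
    def test_two_blobs_split_perfectly(self):
        rng = np.random.default_rng(1)
        m, truth = blob_matrix(rng, [0.0, 8.0])
        assign, _ = hierarchical_cluster(m, k=2)
        assert adjusted_rand_score(truth, assign.labels) == 1.0

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(4, 6)))
        assign, _ = hierarchical_cluster(m, k=6)
        assert assign.labels.nunique() == 6

    def test_average_linkage_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(10, 12)))
        _, tree = hierarchical_cluster(m, k=3)
        heights = tree[:, 2]
        assert (np.diff(heights) >= -1e-9).all()

    def test_composition_table(self):
        rng = np.random.default_rng(4)
        m, truth = blob_matrix(rng, [0.0, 8.0], n_per=5)
        assign, _ = hierarchical_cluster(m, k=2)
        comp = assign.composition(pd.Series(truth, index=m.columns))
        assert comp.to_numpy().sum() == 10
        assert (comp.sum(axis=1) == assign.labels.value_counts().sort_index()).all()


class TestPca:
    def test_line_collapses_to_pc1(self):
        s = np.linspace(0, 1, 12)
        m = pd.DataFrame(np.outer(np.arange(5), s))
        proj = pca_project(m)
        assert np.allclose(proj["PC2"], 0.0, atol=1e-9)
        assert proj["PC1"].std() > 0

    def test_rotation_preserves_distances(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 10))
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        proj_a = pca_project(pd.DataFrame(x), 2).to_numpy()
        proj_b = pca_project(pd.DataFrame(q @ x), 2).to_numpy()
        d_a = np.linalg.norm(proj_a[:, None] - proj_a[None], axis=-1)
        d_b = np.linalg.norm(proj_b[:, None] - proj_b[None], axis=-1)
        assert np.allclose(d_a, d_b, atol=1e-8)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            m = pd.DataFrame(rng.normal(size=(5, 8)))
            proj = pca_project(m, 2).to_numpy()
            x = m.to_numpy().T
            xc = x - x.mean(axis=0)
            vals, vecs = np.linalg.eigh(np.cov(xc.T, bias=False))
            order = np.argsort(vals)[::-1]
            for j in range(2):
                v = vecs[:, order[j]]
                ref = xc @ v
                agree = min(
                    np.abs(proj[:, j] - ref).max(), np.abs(proj[:, j] + ref).max()
                )
                assert agree < 1e-8


class TestKmeans:
    def test_recovers_planted_centroids(self):
        rng = np.random.default_rng(7)
        m, truth = blob_matrix(rng, [0.0, 5.0, 10.0, 15.0, 20.0], n_per=8)
        assign = kmeans_cluster(m, k=5, seed=0)
        assert adjusted_rand_score(truth, assign.labels) >= 0.9

    def test_k1_single_cluster(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(size=(4, 9)))
        assert kmeans_cluster(m, k=1, seed=0).labels.nunique() == 1

    def test_duplicate_points_same_cluster(self):
        col = np.array([1.0, 2.0, 3.0])
        m = pd.DataFrame({"a": col, "b": col, "c": col + 10, "d": col + 10})
        labels = kmeans_cluster(m, k=2, seed=0).labels
        assert labels["a"] == labels["b"]
        assert labels["c"] == labels["d"]


class TestKaplanMeier:
    def test_hand_worked_curve(self):
        curve = km_estimate([1, 2, 3], [1, 1, 0])
        assert curve.at(1) == pytest.approx(2 / 3)
        assert curve.at(2) == pytest.approx(1 / 3)
        assert curve.at(3) == pytest.approx(1 / 3)
        assert curve.at(0.5) == 1.0

    def test_no_events_flat_at_one(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert curve.event_times.size == 0
        assert curve.at(10) == 1.0

    def test_all_events_reach_zero(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert curve.survival[-1] == pytest.approx(0.0)

    def test_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(10, 50)
        events = rng.integers(0, 2, 50)
        curve = km_estimate(times, events)
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert ((curve.survival >= 0) & (curve.survival <= 1)).all()

    def test_matches_lifelines(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            times = rng.exponential(10, 40)
            events = rng.integers(0, 2, 40)
            curve = km_estimate(times, events)
            kmf = KaplanMeierFitter().fit(times, events)
            for t, s in zip(curve.event_times, curve.survival):
                assert s == pytest.approx(
                    float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
                )


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 0, 1, 1])
        res = logrank_test([(times, events), (times, events)])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_hand_oracle_small_dataset(self):
        # group A: events at 1, 2; group B: event at 3, censored at 2
        res = logrank_test([([1.0, 2.0], [1, 1]), ([3.0, 2.0], [1, 0])])
        # t=1: n=(2,2), d=1 -> E_A=0.5, V=0.25
        # t=2: n=(1,2), d=1 -> E_A=1/3, V=2/9
        # t=3: n=(0,1), d=1 -> E_A=0,  V=0
        o_minus_e = 2 - (0.5 + 1 / 3)
        var = 0.25 + 2 / 9
        assert res.statistic == pytest.approx(o_minus_e**2 / var, abs=1e-10)

    def test_matches_lifelines_on_random_data(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            g = int(rng.integers(2, 5))
            times, events, labels = [], [], []
            for gi in range(g):
                n = int(rng.integers(10, 25))
                times += list(rng.exponential(rng.uniform(5, 20), n))
                events += list(rng.integers(0, 2, n))
                labels += [gi] * n
            groups = [
                (
                    [t for t, l in zip(times, labels) if l == gi],
                    [e for e, l in zip(events, labels) if l == gi],
                )
                for gi in range(g)
            ]
            res = logrank_test(groups)
            ref = multivariate_logrank_test(times, labels, events)
            assert res.statistic == pytest.approx(ref.test_statistic, abs=1e-8)
            assert res.p == pytest.approx(ref.p_value, abs=1e-10)

    def test_invariant_to_group_relabeling(self):
        rng = np.random.default_rng(12)
        groups = [
            (rng.exponential(10, 20), rng.integers(0, 2, 20)) for _ in range(3)
        ]
        a = logrank_test(groups)
        b = logrank_test(groups[::-1])
        assert a.statistic == pytest.approx(b.statistic, abs=1e-10)


class TestDichotomize:
    def test_median_split(self):
        assert list(dichotomize_by_median([1, 2, 3, 4])) == [
            "low", "low", "high", "high",
        ]

    def test_value_at_median_is_high(self):
        assert list(dichotomize_by_median([1, 2, 3])) == ["low", "high", "high"]

    def test_constant_vector_all_high(self):
        assert set(dichotomize_by_median([5, 5, 5])) == {"high"}
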
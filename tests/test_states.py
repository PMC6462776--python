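"""L1 k-means, cluster validity / elbow selection, state dynamics metrics,
and stability resampling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from dynstates import states as st


def blobs(rng, centers, n_per, spread):
    X, lab = [], []
    for i, c in enumerate(centers):
        X.append(np.asarray(c) + spread * rng.standard_normal((n_per, len(c))))
        lab.extend([i] * n_per)
    return np.vstack(X), np.array(lab)


class TestKmeansL1:
    def test_k1_centroid_is_componentwise_median(self, rng):
        X = rng.standard_normal((21, 4))
        m = st.kmeans_l1(X, 1, n_init=1, seed=0)
        np.testing.assert_allclose(m.centroids[0], np.median(X, axis=0))
        expected = np.abs(X - np.median(X, axis=0)).sum()
        assert abs(m.objective - expected) < 1e-10

    def test_separated_blobs_recovered_exactly(self, rng):
        X, lab = blobs(rng, [(0, 0), (10, 10), (-10, 10)], 30, 0.5)
        m = st.kmeans_l1(X, 3, n_init=20, seed=1)
        # same partition up to label permutation
        table = pd.crosstab(lab, m.assignments).to_numpy()
        assert (table > 0).sum() == 3

    def test_objective_equals_exhaustive_partition_minimum(self, rng):
        X = rng.standard_normal((6, 2))
        best = np.inf
        for assign in itertools.product([0, 1], repeat=6):
            assign = np.array(assign)
            if len(np.unique(assign)) < 2:
                continue
            obj = 0.0
            for j in (0, 1):
                sub = X[assign == j]
                obj += np.abs(sub - np.median(sub, axis=0)).sum()
            best = min(best, obj)
        m = st.kmeans_l1(X, 2, n_init=50, seed=2)
        assert abs(m.objective - best) < 1e-12

    def test_objective_non_increasing_within_one_init(self, rng):
        # instrument a single run by replaying Lloyd iterations manually
        X = rng.standard_normal((40, 3))
        C = X[:4].copy()
        prev = np.inf
        for _ in range(10):
            lab, dist = st._l1_assign(X, C)
            obj = dist.sum()
            assert obj <= prev + 1e-12
            prev = obj
            for j in range(4):
                if np.any(lab == j):
                    C[j] = np.median(X[lab == j], axis=0)

    def test_rows_fewer_than_k_rejected(self, rng):
        with pytest.raises(ValueError):
            st.kmeans_l1(rng.standard_normal((2, 2)), 3)


class TestValidityAndElbow:
    def test_zero_within_distance(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        m = st.kmeans_l1(X, 2, n_init=5, seed=0)
        assert st.cluster_validity(X, m) == 0.0

    def test_hand_computed_ratio(self):
        # two singleton-centroid clusters at L1 distance 10, rows at distance 1
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [11.0, 0.0], [9.0, 0.0]])
        m = st.ClusterModel(k=2, centroids=np.array([[0.0, 0.0], [10.0, 0.0]]),
                            assignments=np.array([0, 0, 1, 1]),
                            objective=4.0, n_init=1, seed=None)
        assert abs(st.cluster_validity(X, m) - 1.0 / 10.0) < 1e-12

    def test_doubling_separation_halves_ratio(self, rng):
        X1, _ = blobs(rng, [(0, 0), (8, 0)], 40, 0.5)
        X2, _ = blobs(rng, [(0, 0), (16, 0)], 40, 0.5)
        m1 = st.kmeans_l1(X1, 2, n_init=10, seed=3)
        m2 = st.kmeans_l1(X2, 2, n_init=10, seed=3)
        r1, r2 = st.cluster_validity(X1, m1), st.cluster_validity(X2, m2)
        assert abs(r2 / r1 - 0.5) < 0.1

    def test_identical_centroids_rejected(self):
        X = np.zeros((4, 2))
        m = st.ClusterModel(k=2, centroids=np.zeros((2, 2)),
                            assignments=np.array([0, 0, 1, 1]),
                            objective=0.0, n_init=1, seed=None)
        with pytest.raises(ValueError, match="between"):
            st.cluster_validity(X, m)

    def test_sharp_kink_found(self):
        ks = np.arange(2, 9)
        v = np.where(ks <= 4, 10.0 - 3.0 * (ks - 2), 4.0 - 0.1 * (ks - 4))
        k_star, has_elbow = st.find_elbow(ks, v)
        assert k_star == 4 and has_elbow

    def test_linear_curve_flags_no_elbow(self):
        ks = np.arange(2, 9)
        k_star, has_elbow = st.find_elbow(ks, 10.0 - ks.astype(float))
        assert k_star == 2 and not has_elbow

    def test_select_k_on_three_blobs(self, rng):
        X, _ = blobs(rng, [(0, 0, 0), (12, 0, 0), (0, 12, 0)], 50, 0.8)
        k_star, curve, _ = st.select_k(X, range(2, 7), n_init=10, seed=4)
        assert k_star == 3
        assert list(curve["k"]) == [2, 3, 4, 5, 6]


class TestStateMetrics:
    def test_constant_sequence(self):
        per_state, per_subj = st.state_metrics({"s": np.ones(107, dtype=int)}, states=[1])
        row = per_state.iloc[0]
        assert row["frequency"] == 1.0 and row["mean_dwell"] == 107
        assert per_subj.iloc[0]["n_transitions"] == 0
        assert per_subj.iloc[0]["intertransition_interval"] == 107

    def test_hand_enumerated_runs(self):
        seq = np.array([1, 1, 2, 2, 2, 1])
        per_state, per_subj = st.state_metrics({"s": seq}, states=[1, 2])
        f = per_state.set_index("state")
        assert f.loc[1, "frequency"] == 0.5 and f.loc[2, "frequency"] == 0.5
        assert f.loc[1, "mean_dwell"] == 1.5 and f.loc[2, "mean_dwell"] == 3.0
        assert per_subj.iloc[0]["n_transitions"] == 2
        assert per_subj.iloc[0]["intertransition_interval"] == 2.0

    def test_alternating_sequence(self):
        seq = np.tile([1, 2], 5)
        per_state, per_subj = st.state_metrics({"s": seq}, states=[1, 2])
        assert per_subj.iloc[0]["n_transitions"] == 9
        assert (per_state["mean_dwell"] == 1.0).all()

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError, match="unknown state"):
            st.state_metrics({"s": np.array([1, 5])}, states=[1, 2])

    @settings(max_examples=50, deadline=None)
    @given(hst.lists(hst.integers(min_value=1, max_value=4), min_size=1, max_size=60))
    def test_invariants_for_arbitrary_sequences(self, seq):
        seq = np.array(seq)
        per_state, per_subj = st.state_metrics({"s": seq}, states=[1, 2, 3, 4])
        W = seq.size
        # frequencies sum to 1
        assert abs(per_state["frequency"].sum() - 1.0) < 1e-12
        # sum of run lengths = W; transitions = runs - 1
        labs, lens = st.run_lengths(seq)
        assert lens.sum() == W
        n_trans = per_subj.iloc[0]["n_transitions"]
        assert n_trans == labs.size - 1 and n_trans <= W - 1
        assert abs(per_subj.iloc[0]["intertransition_interval"] - W / (n_trans + 1)) < 1e-12


class TestStability:
    def test_duplicated_halves_perfectly_similar(self, rng):
        # centroids need enough features for correlation to be informative
        c = np.eye(3, 8) * 10
        X, _ = blobs(rng, [c[0], c[1], c[2]], 20, 0.3)
        X2 = np.vstack([X, X])
        subj = np.concatenate([np.repeat(np.arange(6), 10), np.repeat(np.arange(6, 12), 10)])
        rep = st.stability_analysis(X2, subj, 3, scheme="split_half",
                                    n_replicates=5, n_init=10, seed=0)
        assert np.all(rep.similarities > 0.99)

    def test_bootstrap_on_separable_blobs_is_stable(self, rng):
        c = np.eye(3, 8) * 12
        X, _ = blobs(rng, [c[0], c[1], c[2]], 60, 0.5)
        subj = np.repeat(np.arange(18), 10)
        rep = st.stability_analysis(X, subj, 3, scheme="bootstrap",
                                    n_replicates=20, n_init=10, seed=1)
        assert np.all(rep.median_similarity > 0.95)

    def test_unseparable_data_materially_less_stable(self, rng):
        c = np.eye(3, 8) * 12
        Xsep, _ = blobs(rng, [c[0], c[1], c[2]], 60, 0.5)
        Xnull = rng.standard_normal((180, 8))
        subj = np.repeat(np.arange(18), 10)
        rep_sep = st.stability_analysis(Xsep, subj, 3, scheme="bootstrap",
                                        n_replicates=20, n_init=10, seed=2)
        rep_null = st.stability_analysis(Xnull, subj, 3, scheme="bootstrap",
                                         n_replicates=20, n_init=10, seed=2)
        assert (np.median(rep_sep.similarities) -
                np.median(rep_null.similarities)) > 0.2


class TestRelabel:
    def test_states_ordered_by_descending_occupancy(self, rng):
        X, _ = blobs(rng, [(0, 0), (10, 0)], 10, 0.2)
        X = np.vstack([X, X[10:]])  # cluster 1 now has twice the rows
        m = st.kmeans_l1(X, 2, n_init=10, seed=5)
        m, _ = st.relabel_by_frequency(m)
        counts = np.bincount(m.assignments)
        assert counts[0] >= counts[1]
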
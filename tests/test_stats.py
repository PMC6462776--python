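"""Rank statistics vs sort-based oracles, Dunn/BH, permutation MANOVA,
effect sizes, and summary-statistics demographics tests."""

import numpy as np
import pandas as pd
import pytest

from dynstates import stats


def midranks(x):
    """Independent sort-based midrank oracle."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def kw_oracle(groups):
    pooled = np.concatenate(groups)
    r = midranks(pooled)
    N = pooled.size
    pos = 0
    H = 0.0
    for g in groups:
        rs = r[pos:pos + len(g)].sum()
        H += rs**2 / len(g)
        pos += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3 * (N + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    c = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    return H / c


class TestKruskalWallis:
    def test_hand_computed_three_groups(self):
        H, df, p = stats.kruskal_wallis([np.array([1, 2]), np.array([3, 4]),
                                         np.array([5, 6])])
        assert abs(H - 32 / 7) < 1e-10  # 12/42 * 89.5 - 21
        assert df == 2

    def test_identical_values_give_zero(self):
        H, _, p = stats.kruskal_wallis([np.ones(5), np.ones(4)])
        assert H == 0.0 and p == 1.0

    def test_matches_sort_based_oracle_on_random_data(self, rng):
        for _ in range(10):
            gs = [rng.integers(0, 8, rng.integers(4, 12)).astype(float)
                  for _ in range(3)]
            H, _, _ = stats.kruskal_wallis(gs)
            assert abs(H - kw_oracle(gs)) < 1e-10


class TestDunn:
    def test_identical_groups_z_zero(self):
        out = stats.dunn_posthoc([np.arange(6.0), np.arange(6.0)])
        assert abs(out["z"].iloc[0]) < 1e-12
        assert out["p"].iloc[0] == 1.0

    def test_bh_step_up_by_hand(self):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def test_matches_independent_oracle(self, rng):
        gs = [rng.normal(i, 1, 8) for i in range(3)]
        out = stats.dunn_posthoc(gs, labels=["a", "b", "c"])
        pooled = np.concatenate(gs)
        r = midranks(pooled)
        N = pooled.size
        _, counts = np.unique(pooled, return_counts=True)
        var = N * (N + 1) / 12 - np.sum(counts**3 - counts) / (12 * (N - 1))
        rbar = [r[:8].mean(), r[8:16].mean(), r[16:].mean()]
        z01 = (rbar[0] - rbar[1]) / np.sqrt(var * (1 / 8 + 1 / 8))
        row = out[(out.group_a == "a") & (out.group_b == "b")]
        assert abs(row["z"].iloc[0] - z01) < 1e-10

    def test_bh_adjustment_monotone_and_bounded(self, rng):
        gs = [rng.normal(i * 0.5, 1, 10) for i in range(4)]
        out = stats.dunn_posthoc(gs)
        assert (out["p_adj"] >= out["p"] - 1e-15).all()
        assert (out["p_adj"] <= 1.0).all()
        s = out.sort_values("p")
        assert s["p_adj"].is_monotonic_increasing


class TestManova:
    def test_complete_separation_minimal_p(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (12, 2)), rng.normal(50, 0.1, (12, 2))])
        g = np.repeat([0, 1], 12)
        _, p = stats.nonparametric_manova(X, g, n_perm=499, seed=0)
        assert abs(p - 1 / 500) < 1e-12

    def test_invariant_to_column_scaling(self, rng):
        X = rng.standard_normal((24, 3))
        g = np.repeat([0, 1, 2], 8)
        s1, p1 = stats.nonparametric_manova(X, g, n_perm=199, seed=5)
        s2, p2 = stats.nonparametric_manova(X * [10.0, 0.01, 1e6], g,
                                            n_perm=199, seed=5)
        assert abs(s1 - s2) < 1e-10 and p1 == p2

    def test_constant_column_named(self, rng):
        X = rng.standard_normal((15, 3))
        X[:, 1] = 2.0
        with pytest.raises(ValueError, match="column 1"):
            stats.nonparametric_manova(X, np.repeat([0, 1, 2], 5))

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="too few"):
            stats.nonparametric_manova(rng.standard_normal((4, 3)),
                                       np.array([0, 0, 1, 1]))


class TestEffectSize:
    @pytest.mark.parametrize("z,n,expected", [(0.0, 10, 0.0), (4.0, 16, 1.0),
                                              (2.0, 16, 0.25)])
    def test_formula(self, z, n, expected):
        assert abs(stats.effect_size_r2(z, n) - expected) < 1e-12

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            stats.effect_size_r2(1.0, 0)


class TestSpearman:
    def test_monotone_pairs(self):
        m = pd.DataFrame({"x": [1.0, 2, 3, 5, 9]})
        up = pd.DataFrame({"u": [2.0, 4, 5, 8, 20]})
        down = pd.DataFrame({"d": [9.0, 5, 4, 2, 1]})
        assert abs(stats.spearman_clinical(m, up)[0].rho - 1.0) < 1e-12
        assert abs(stats.spearman_clinical(m, down)[0].rho + 1.0) < 1e-12

    def test_matches_rank_pearson_oracle(self, rng):
        x = rng.standard_normal(20)
        y = 0.5 * x + rng.standard_normal(20)
        cc = stats.spearman_clinical(pd.DataFrame({"x": x}), pd.DataFrame({"y": y}))[0]
        rx, ry = midranks(x), midranks(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert abs(cc.rho - oracle) < 1e-12

    def test_pairwise_complete_missing_handling(self, rng):
        x = rng.standard_normal(12)
        y = x.copy()
        y[3] = np.nan
        cc = stats.spearman_clinical(pd.DataFrame({"x": x}), pd.DataFrame({"y": y}))[0]
        assert cc.n == 11 and cc.rho == 1.0


class TestMannWhitney:
    def test_disjoint_groups_give_zero_u(self):
        u, _ = stats.mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0

    def test_identical_groups_give_half_max(self):
        u, _ = stats.mann_whitney(np.ones(4), np.ones(5))
        assert u == 10.0  # 4*5/2

    def test_exact_p_matches_enumeration_for_small_samples(self, rng):
        import itertools
        a = rng.standard_normal(4)
        b = rng.standard_normal(5)
        u_obs, p = stats.mann_whitney(a, b)
        # enumerate all placements of group-a ranks among the 9 values
        pooled = np.concatenate([a, b])
        ranks = midranks(pooled)
        count = total = 0
        for combo in itertools.combinations(range(9), 4):
            r = ranks[list(combo)].sum()
            u1 = r - 4 * 5 / 2
            u = min(u1, 20 - u1)
            count += u <= u_obs + 1e-12
            total += 1
        assert abs(p - count / total) < 1e-6


class TestDemographicsEngine:
    def test_chi_square_warns_on_tiny_expected_counts(self):
        with pytest.warns(UserWarning, match="expected cell"):
            chi2, _, _ = stats.chi_square([[1, 0], [0, 1]])
        assert np.isfinite(chi2)

    def test_anova_from_summary_matches_raw_anova(self, rng):
        from scipy.stats import f_oneway
        gs = [rng.normal(i * 0.3, 1, 12) for i in range(3)]
        F_raw, p_raw = f_oneway(*gs)
        F, _, p = stats.anova_from_summary([g.mean() for g in gs],
                                           [g.std(ddof=1) for g in gs],
                                           [len(g) for g in gs])
        assert abs(F - F_raw) < 1e-10 and abs(p - p_raw) < 1e-10

    def test_demographics_table_from_manifest(self, rng):
        man = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(60)],
            "group": np.repeat(["HC", "AD", "DLB"], 20),
            "gender": rng.integers(0, 2, 60),
            "age": rng.normal(76, 7, 60),
        })
        out = stats.demographics_table(man, categorical=["gender"], continuous=["age"])
        assert set(out["test"]) == {"chi-square", "one-way ANOVA"}
        assert ((out["p"] >= 0) & (out["p"] <= 1)).all()
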
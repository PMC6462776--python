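"""Sliding-window connectivity: tapers, weighted covariance, graphical
LASSO (with an independent optimizer oracle), lambda cross-validation,
Fisher z, residualization, and temporal-variability summaries."""

import numpy as np
import pytest
from scipy.optimize import minimize

from dynstates import dfc


# ---------------------------------------------------------------------------
# Taper and window arithmetic
# ---------------------------------------------------------------------------


class TestTaper:
    def test_default_is_length_22_normalized_symmetric(self):
        t = dfc.make_taper()
        assert t.weights.shape == (22,)
        assert abs(t.weights.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(t.weights, t.weights[::-1], atol=1e-12)

    def test_sigma_to_zero_limit_is_uniform(self):
        t = dfc.make_taper(10, sigma=1e-6)
        assert np.max(np.abs(t.weights - 0.1)) < 1e-6

    def test_center_heavier_than_edges(self):
        t = dfc.make_taper()
        assert t.weights[11] > t.weights[0]

    def test_width_below_two_rejected(self):
        with pytest.raises(ValueError):
            dfc.make_taper(1)


class TestWindowCount:
    @pytest.mark.parametrize("T,w,step,expected", [
        (128, 22, 1, 107),
        (22, 22, 1, 1),
        (128, 18, 1, 111),
        (128, 28, 1, 101),
        (100, 20, 5, 17),
    ])
    def test_formula(self, T, w, step, expected):
        assert dfc.window_count(T, w, step) == expected

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            dfc.window_count(20, 22)


class TestWindowedCovariance:
    def test_uniform_taper_equals_plain_sample_covariance(self, rng):
        X = rng.standard_normal((60, 4))
        taper = dfc.make_taper(20, sigma=1e-6)
        covs = dfc.windowed_covariance(X, taper)
        oracle = np.cov(X[:20].T)
        assert np.max(np.abs(covs[0] - oracle)) < 1e-6

    def test_constant_signal_gives_zero_covariance(self):
        X = np.full((50, 3), 2.0)
        covs = dfc.windowed_covariance(X, dfc.make_taper(20))
        np.testing.assert_allclose(covs, 0.0, atol=1e-12)

    def test_107_windows_for_study_geometry(self, rng):
        X = rng.standard_normal((128, 5))
        covs = dfc.windowed_covariance(X, dfc.make_taper(22, 3.0))
        assert covs.shape == (107, 5, 5)


# ---------------------------------------------------------------------------
# Graphical LASSO
# ---------------------------------------------------------------------------


def oracle_glasso_objective(S, lam, seed=0):
    """Independent optimizer: minimize the penalized negative log-likelihood
    over SPD matrices by L-BFGS-B on a positive/negative split of the
    off-diagonal entries (numerical gradients)."""
    p = S.shape[0]
    iu = np.triu_indices(p, k=1)
    n_off = iu[0].size

    def unpack(theta):
        d = theta[:p]
        a = theta[p:p + n_off]
        b = theta[p + n_off:]
        P = np.zeros((p, p))
        P[np.diag_indices(p)] = d
        P[iu] = a - b
        P[(iu[1], iu[0])] = a - b
        return P, a, b

    def f(theta):
        P, a, b = unpack(theta)
        sign, logdet = np.linalg.slogdet(P)
        if sign <= 0:
            return 1e10
        # both triangles of the symmetric precision carry the penalty
        return -logdet + float(np.trace(S @ P)) + 2.0 * lam * float(np.sum(a + b))

    rng = np.random.default_rng(seed)
    best = np.inf
    for trial in range(4):
        d0 = 1.0 / np.maximum(np.diag(S), 1e-3)
        x0 = np.concatenate([d0, np.zeros(2 * n_off)])
        if trial > 0:
            x0 = x0 + 0.05 * rng.standard_normal(x0.size)
            x0[:p] = np.abs(x0[:p]) + 0.1
        bounds = [(1e-8, None)] * p + [(0.0, None)] * (2 * n_off)
        res = minimize(f, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12})
        best = min(best, res.fun)
    return best


class TestGraphicalLasso:
    def test_diagonal_input_lambda_zero_inverts_elementwise(self):
        S = np.diag([2.0, 0.5, 4.0])
        prec, cov = dfc.graphical_lasso(S, 0.0)
        np.testing.assert_allclose(prec, np.diag([0.5, 2.0, 0.25]), atol=1e-12)
        np.testing.assert_allclose(cov, S)

    def test_large_lambda_zeros_all_offdiagonals(self, rng):
        A = rng.standard_normal((4, 4))
        S = A @ A.T + 4 * np.eye(4)
        lam = np.abs(S - np.diag(np.diag(S))).max() * 1.01
        prec, _ = dfc.graphical_lasso(S, lam, tol=1e-8)
        off = prec - np.diag(np.diag(prec))
        assert np.max(np.abs(off)) < 1e-6

    def test_objective_matches_independent_optimizer(self, rng):
        A = rng.standard_normal((3, 3))
        S = A @ A.T + np.eye(3)
        lam = 0.1
        prec, _ = dfc.graphical_lasso(S, lam, max_iter=2000, tol=1e-12)
        ours = dfc.glasso_objective(S, prec, lam)
        oracle = oracle_glasso_objective(S, lam)
        assert abs(ours - oracle) < 1e-6

    def test_precision_positive_definite_for_positive_lambda(self, rng):
        X = rng.standard_normal((15, 6))   # rank-deficient sample cov
        S = np.cov(X.T)
        prec, _ = dfc.graphical_lasso(S, 0.2)
        assert np.linalg.eigvalsh(prec)[0] > 0

    def test_lambda_to_zero_recovers_input_covariance(self, rng):
        A = rng.standard_normal((4, 4))
        S = A @ A.T + 2 * np.eye(4)
        _, cov = dfc.graphical_lasso(S, 1e-8, max_iter=5000, tol=1e-12)
        assert np.max(np.abs(cov - S)) < 1e-4


class TestSelectLambda:
    def test_singleton_grid_returned(self, rng):
        X = rng.standard_normal((80, 4))
        covs = dfc.windowed_covariance(X, dfc.make_taper(20))
        sel = dfc.select_lambda(covs, grid=[0.3], n_folds=5)
        assert sel.chosen == 0.3

    def test_heldout_loglik_matches_density_oracle(self, rng):
        # 2-variable closed form: ll = -0.5 (p log 2pi - logdet P + tr(S P))
        X = rng.standard_normal((60, 2)) @ np.array([[1.0, 0.4], [0.0, 0.9]])
        covs = dfc.windowed_covariance(X, dfc.make_taper(15))
        grid = [0.2]
        n_folds = 4
        sel = dfc.select_lambda(covs, grid=grid, n_folds=n_folds)
        W = covs.shape[0]
        bounds = np.linspace(0, W, n_folds + 1).astype(int)
        for f in range(n_folds):
            test = np.arange(bounds[f], bounds[f + 1])
            train = np.setdiff1d(np.arange(W), test)
            prec, _ = dfc.graphical_lasso(covs[train].mean(axis=0), 0.2)
            sign, logdet = np.linalg.slogdet(prec)
            lls = [-0.5 * (2 * np.log(2 * np.pi) - logdet + np.trace(covs[t] @ prec))
                   for t in test]
            assert abs(sel.fold_loglik[0, f] - np.mean(lls)) < 1e-8

    def test_fewer_windows_than_folds_raises(self, rng):
        X = rng.standard_normal((30, 3))
        covs = dfc.windowed_covariance(X, dfc.make_taper(20))
        with pytest.raises(ValueError, match="smaller n_folds"):
            dfc.select_lambda(covs, grid=[0.1], n_folds=20)

    def test_sparse_precision_data_yields_interior_maximizer(self):
        # with few samples relative to dimension, some shrinkage must help:
        # the CV curve should peak strictly inside the grid most of the time
        p, T, w = 15, 60, 16
        prec_true = np.eye(p)
        idx = [(i, i + 1) for i in range(0, p - 1, 3)]
        for i, j in idx:
            prec_true[i, j] = prec_true[j, i] = 0.4
        cov_true = np.linalg.inv(prec_true)
        L = np.linalg.cholesky(cov_true)
        grid = np.geomspace(1e-3, 1.0, 12)
        interior = 0
        n_rep = 10
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            X = rng.standard_normal((T, p)) @ L.T
            covs = dfc.windowed_covariance(X, dfc.make_taper(w))
            sel = dfc.select_lambda(covs, grid=grid, n_folds=5)
            if grid[0] < sel.chosen < grid[-1]:
                interior += 1
        assert interior >= 0.9 * n_rep


# ---------------------------------------------------------------------------
# Fisher z, residualization, variability
# ---------------------------------------------------------------------------


class TestFisherZ:
    def test_closed_form_values(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        z = dfc.to_fisher_z(S)
        assert abs(z[0, 1] - np.arctanh(0.5)) < 1e-12
        assert z[0, 0] == 0.0

    def test_odd_function(self, rng):
        r = rng.uniform(-0.9, 0.9, 10)
        for v in r:
            S = np.array([[1.0, v], [v, 1.0]])
            Sn = np.array([[1.0, -v], [-v, 1.0]])
            assert abs(dfc.to_fisher_z(S)[0, 1] + dfc.to_fisher_z(Sn)[0, 1]) < 1e-12

    def test_perfect_correlation_rejected_with_location(self):
        S = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="window 0"):
            dfc.to_fisher_z(S[None])


class TestResidualize:
    def test_orthogonal_covariate_is_noop(self, rng):
        import pandas as pd
        n = 20
        cov = rng.standard_normal(n)
        z = rng.standard_normal((n, 5, 3))
        # make every cell exactly orthogonal to the centered covariate
        cc = cov - cov.mean()
        Y = z.reshape(n, -1)
        Y = Y - np.outer(cc, cc @ Y) / (cc @ cc)
        z = Y.reshape(n, 5, 3)
        out = dfc.residualize(z, pd.DataFrame({"age": cov}))
        np.testing.assert_allclose(out, z, atol=1e-10)

    def test_exact_linear_dependence_removed(self, rng):
        import pandas as pd
        n = 25
        age = rng.uniform(60, 90, n)
        z = np.outer(age, np.ones(6)).reshape(n, 2, 3) * 0.1
        out = dfc.residualize(z, pd.DataFrame({"age": age}))
        resid = out - out.mean(axis=0)
        assert resid.var() < 1e-10 * z.var()

    def test_idempotent(self, rng):
        import pandas as pd
        z = rng.standard_normal((15, 4, 3))
        cov = pd.DataFrame({"age": rng.uniform(60, 90, 15),
                            "gender": rng.integers(0, 2, 15)})
        once = dfc.residualize(z, cov)
        twice = dfc.residualize(once, cov)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_collinear_design_named(self, rng):
        import pandas as pd
        a = rng.standard_normal(12)
        cov = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(ValueError, match="collinear"):
            dfc.residualize(rng.standard_normal((12, 2, 2)), cov)


class TestVariability:
    def test_identical_windows_zero_sd(self):
        z = np.tile(np.eye(4)[None], (6, 1, 1)).astype(float)
        v = dfc.connectivity_variability(z)
        np.testing.assert_allclose(v.sd_matrix, 0.0)
        assert v.overall_mean == 0.0

    def test_two_point_closed_form(self):
        base = np.zeros((3, 3))
        base[0, 1] = base[1, 0] = 0.7
        z = np.stack([base, -base])
        v = dfc.connectivity_variability(z)
        assert abs(v.sd_matrix[0, 1] - 0.7 * np.sqrt(2)) < 1e-12

    def test_shapes_for_27_networks(self, rng):
        z = rng.standard_normal((10, 27, 27))
        z = z + z.transpose(0, 2, 1)
        v = dfc.connectivity_variability(z)
        assert v.sd_matrix.shape == (27, 27)
        assert v.network_mean.shape == (27,)
        tri = v.sd_matrix[np.triu_indices(27, 1)]
        assert abs(v.overall_mean - tri.mean()) < 1e-12

    def test_single_window_rejected(self):
        with pytest.raises(ValueError):
            dfc.connectivity_variability(np.zeros((1, 3, 3)))
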
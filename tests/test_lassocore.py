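import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glmqtl import lassocore as lc
from glmqtl.glmfam import make_family


def _instance(n=50, k=10, seed=0, signal=None):
    """Random weighted working data with an unpenalized intercept column."""
    rng = np.random.default_rng(seed)
    X = np.hstack([np.ones((n, 1)), rng.standard_normal((n, k))])
    b = np.zeros(k + 1)
    if signal:
        for j, v in signal.items():
            b[j] = v
    z = X @ b + rng.standard_normal(n)
    w = rng.uniform(0.5, 2.0, n)
    pf = np.concatenate([[0.0], np.ones(k)])
    return lc.WorkingData(z=z, X=X, w=w, penalty_factor=pf)


class TestSoftThreshold:
    @pytest.mark.parametrize("rho, lam, out", [(3, 1, 2), (0.5, 1, 0), (-2.5, 1.5, -1)])
    def test_closed_form(self, rho, lam, out):
        assert lc.soft_threshold(rho, lam) == out

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            lc.soft_threshold(1.0, -0.1)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(rho=st.floats(-100, 100), lam=st.floats(0, 100))
    def test_shrinks_toward_zero_preserving_sign(self, rho, lam):
        out = lc.soft_threshold(rho, lam)
        assert abs(out) <= abs(rho) + 1e-12
        assert out == 0 or np.sign(out) == np.sign(rho)


class TestWorkingData:
    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            lc.WorkingData(z=np.array([np.nan]), X=np.ones((1, 1)),
                           w=np.ones(1), penalty_factor=np.ones(1))

    def test_rejects_nonpositive_weights(self):
        with pytest.raises(ValueError):
            lc.WorkingData(z=np.zeros(2), X=np.ones((2, 1)),
                           w=np.array([1.0, 0.0]), penalty_factor=np.ones(1))


class TestCoordinateDescent:
    def test_lambda_max_gives_null_solution(self):
        data = _instance(seed=1)
        lam_max = lc.lambda_path(data, n_lambda=1)[0]
        sol = lc.coordinate_descent(data, lam_max)
        assert sol.n_nonzero == 0
        wn = data.normalized_weights()
        assert sol.intercept == pytest.approx(np.sum(wn * data.z) / np.sum(wn), abs=1e-6)

    def test_unpenalized_matches_weighted_least_squares(self):
        data = _instance(n=50, k=3, seed=2)
        sol = lc.coordinate_descent(data, 0.0, tol=1e-12)
        W = np.diag(data.normalized_weights())
        oracle = np.linalg.solve(data.X.T @ W @ data.X, data.X.T @ W @ data.z)
        np.testing.assert_allclose(sol.coef, oracle, atol=1e-6)

    def test_orthogonal_design_closed_form(self):
        rng = np.random.default_rng(3)
        n = 64
        A = rng.standard_normal((n, 2))
        Q, _ = np.linalg.qr(A)
        X = Q * np.sqrt(n)  # (1/n) X'X = I
        z = rng.standard_normal(n) + X @ np.array([1.0, -0.5])
        data = lc.WorkingData(z=z, X=X, w=np.ones(n), penalty_factor=np.ones(2))
        lam = 0.3
        sol = lc.coordinate_descent(data, lam, tol=1e-12)
        rho = X.T @ z / n
        np.testing.assert_allclose(sol.coef, lc.soft_threshold(rho, lam), atol=1e-8)

    def test_kkt_conditions_hold_at_solution(self):
        data = _instance(n=60, k=15, seed=4, signal={1: 2.0, 5: -1.0})
        for lam in (0.02, 0.1, 0.5):
            sol = lc.coordinate_descent(data, lam, tol=1e-10)
            assert lc.kkt_violation(data, sol.coef, lam) < 1e-6

    def test_solution_invariant_to_column_order(self):
        data = _instance(n=50, k=8, seed=5, signal={2: 1.5})
        lam = 0.1
        sol = lc.coordinate_descent(data, lam, tol=1e-12)
        perm = np.random.default_rng(0).permutation(9)
        data_p = lc.WorkingData(z=data.z, X=data.X[:, perm], w=data.w,
                                penalty_factor=data.penalty_factor[perm])
        sol_p = lc.coordinate_descent(data_p, lam, tol=1e-12)
        np.testing.assert_allclose(sol_p.coef, sol.coef[perm], atol=1e-8)

    def test_debug_mode_objective_monotone(self):
        data = _instance(n=40, k=6, seed=6, signal={1: 1.0})
        sol = lc.coordinate_descent(data, 0.05, debug=True)
        assert sol.converged  # the debug path asserts monotonicity internally


class TestLambdaPath:
    def test_single_lambda_is_max(self):
        data = _instance(seed=7)
        path = lc.lambda_path(data, n_lambda=1)
        assert path.size == 1
        sol = lc.coordinate_descent(data, path[0])
        assert sol.n_nonzero == 0

    def test_geometric_spacing(self):
        data = _instance(seed=8)
        path = lc.lambda_path(data, n_lambda=3, lambda_min_ratio=0.01)
        assert path[1] == pytest.approx(0.1 * path[0], rel=1e-9)
        assert path[2] == pytest.approx(0.01 * path[0], rel=1e-9)

    def test_degenerate_response_warns(self):
        n = 20
        data = lc.WorkingData(z=np.ones(n), X=np.hstack([np.ones((n, 1)),
                              np.random.default_rng(0).standard_normal((n, 2))]),
                              w=np.ones(n), penalty_factor=np.array([0.0, 1.0, 1.0]))
        with pytest.warns(RuntimeWarning):
            path = lc.lambda_path(data)
        assert path[0] == 0.0

    def test_sparsity_decreases_along_path(self):
        data = _instance(n=50, k=20, seed=9, signal={1: 2.0, 7: 1.0, 15: -1.5})
        path = lc.lambda_path(data, n_lambda=10, lambda_min_ratio=0.01)
        warm = None
        nnz = []
        for lam in path:
            sol = lc.coordinate_descent(data, lam, warm_start=warm)
            warm = sol.coef
            nnz.append(sol.n_nonzero)
        assert nnz[-1] >= nnz[0]

    def test_warm_start_equals_cold_start(self):
        data = _instance(n=50, k=20, seed=10, signal={3: 1.0})
        path = lc.lambda_path(data, n_lambda=8)
        warm = None
        for lam in path:
            sol_w = lc.coordinate_descent(data, lam, tol=1e-10, warm_start=warm)
            sol_c = lc.coordinate_descent(data, lam, tol=1e-10)
            np.testing.assert_allclose(sol_w.coef, sol_c.coef, atol=1e-6)
            warm = sol_w.coef


class TestPenalizedGLM:
    def test_gaussian_path_matches_direct_lasso(self):
        fam = make_family("gaussian")
        rng = np.random.default_rng(11)
        n, k = 60, 8
        X = np.hstack([np.ones((n, 1)), rng.standard_normal((n, k))])
        y = X[:, 1] * 1.5 + rng.standard_normal(n)
        pf = np.concatenate([[0.0], np.ones(k)])
        coefs, _ = lc.fit_penalized_glm(y, X, fam, [0.2], pf)
        data = lc.WorkingData(z=y, X=X, w=np.ones(n), penalty_factor=pf)
        sol = lc.coordinate_descent(data, 0.2, tol=1e-10)
        np.testing.assert_allclose(coefs[0], sol.coef, atol=1e-6)

    def test_binomial_coefficients_match_r_glmnet_shape(self):
        """Logistic penalized fit recovers the planted predictor."""
        fam = make_family("binomial")
        rng = np.random.default_rng(12)
        n, k = 200, 10
        X = np.hstack([np.ones((n, 1)), rng.standard_normal((n, k))])
        eta = 1.5 * X[:, 3]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        pf = np.concatenate([[0.0], np.ones(k)])
        lam, coef = lc.bic_select(y, X, fam, pf)
        assert coef[3] != 0
        assert np.count_nonzero(coef[1:]) <= 4


class TestCrossValidate:
    def test_deterministic_given_seed(self):
        fam = make_family("gaussian")
        rng = np.random.default_rng(13)
        n, k = 60, 10
        X = np.hstack([np.ones((n, 1)), rng.standard_normal((n, k))])
        y = X[:, 2] + rng.standard_normal(n)
        pf = np.concatenate([[0.0], np.ones(k)])
        a = lc.cross_validate(y, X, fam, pf, seed=5)
        b = lc.cross_validate(y, X, fam, pf, seed=5)
        assert a.lambda_min == b.lambda_min
        np.testing.assert_allclose(a.mean_deviance, b.mean_deviance)
        assert np.all(np.diff(a.lambdas) < 0)
        assert a.lambda_min in a.lambdas

    def test_pure_noise_selects_sparse_models(self):
        fam = make_family("gaussian")
        pf = np.concatenate([[0.0], np.ones(20)])
        sparse = 0
        runs = 30
        for s in range(runs):
            rng = np.random.default_rng(100 + s)
            X = np.hstack([np.ones((80, 1)), rng.standard_normal((80, 20))])
            y = rng.standard_normal(80)
            cv = lc.cross_validate(y, X, fam, pf, seed=s)
            li = int(np.flatnonzero(cv.lambdas == cv.lambda_min)[0])
            coefs, _ = lc.fit_penalized_glm(y, X, fam, cv.lambdas[: li + 1], pf)
            if np.count_nonzero(coefs[li][1:]) <= 5:
                sparse += 1
        assert sparse >= 0.9 * runs

    def test_strong_predictor_always_selected(self):
        fam = make_family("gaussian")
        pf = np.concatenate([[0.0], np.ones(10)])
        hits = 0
        runs = 30
        for s in range(runs):
            rng = np.random.default_rng(200 + s)
            X = np.hstack([np.ones((200, 1)), rng.standard_normal((200, 10))])
            y = 2.0 * X[:, 4] + rng.standard_normal(200)
            cv = lc.cross_validate(y, X, fam, pf, seed=s)
            li = int(np.flatnonzero(cv.lambdas == cv.lambda_min)[0])
            coefs, _ = lc.fit_penalized_glm(y, X, fam, cv.lambdas[: li + 1], pf)
            if coefs[li][4] != 0:
                hits += 1
        assert hits >= 0.95 * runs

    def test_too_few_folds_rejected(self):
        fam = make_family("gaussian")
        with pytest.raises(ValueError):
            lc.cross_validate(np.zeros(10), np.ones((10, 1)), fam, np.ones(1), folds=1)
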
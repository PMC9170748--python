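"""Single-condition sparse fit: analytic and brute-force oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.linear_model import Lasso

from kldm.model_core import ConditionParams, CountMatrix, EFMatrix, dm_logpmf, gaussian_logpdf_prec
from kldm.single_fit import (
    PenaltyGrid,
    ebic_score,
    estimate_latent_map,
    fit_single_condition,
    otu_filter,
    update_B,
    update_theta,
)


class TestOtuFilter:
    def _cm(self, counts):
        counts = np.asarray(counts)
        return CountMatrix(
            counts,
            [f"s{i}" for i in range(counts.shape[0])],
            [f"o{j}" for j in range(counts.shape[1])],
        )

    def test_identity_when_small(self):
        X = self._cm(np.ones((10, 5), dtype=int))
        Xf, kept = otu_filter(X, 10)
        assert kept == X.otu_ids
        assert np.array_equal(Xf.counts, X.counts)

    def test_keeps_highest_totals(self):
        counts = np.tile(np.arange(1, 11), (6, 1))
        X = self._cm(counts)
        Xf, kept = otu_filter(X, 6)
        assert kept == [f"o{j}" for j in range(4, 10)]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        X = self._cm(rng.integers(1, 50, size=(5, 12)))
        X1, k1 = otu_filter(X, 5)
        X2, k2 = otu_filter(X1, 5)
        assert k1 == k2
        assert np.array_equal(X1.counts, X2.counts)

    def test_rejects_tiny_max_p(self):
        with pytest.raises(ValueError):
            otu_filter(self._cm(np.ones((3, 3), dtype=int)), 1)


class TestUpdateB:
    def test_infinite_penalty_zeroes(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(30, 4))
        M = rng.normal(size=(30, 2))
        B = update_B(Z, M, np.zeros(4), 1e6)
        assert np.allclose(B, 0.0)

    def test_zero_penalty_matches_ols(self):
        rng = np.random.default_rng(2)
        M = rng.normal(size=(50, 3))
        Btrue = rng.normal(size=(3, 4))
        Z = M @ Btrue + 0.01 * rng.normal(size=(50, 4))
        B = update_B(Z, M, np.zeros(4), 0.0)
        Mc = M - M.mean(axis=0)
        ols = np.linalg.lstsq(Mc, Z - Z.mean(axis=0), rcond=None)[0]
        assert np.allclose(B, ols, atol=1e-6)

    def test_scalar_soft_threshold(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(40, 1))
        z = 0.7 * m + 0.05 * rng.normal(size=(40, 1))
        lam = 2.0
        B = update_B(z, m, np.zeros(1), lam)
        mc = m[:, 0] - m[:, 0].mean()
        zc = z[:, 0] - 0.0
        rho = mc @ zc
        expected = np.sign(rho) * max(abs(rho) - lam, 0.0) / (mc @ mc)
        assert B[0, 0] == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("lam", [0.5, 2.0, 8.0])
    def test_matches_sklearn_lasso(self, lam):
        rng = np.random.default_rng(4)
        M = rng.normal(size=(60, 3))
        Z = rng.normal(size=(60, 5))
        B = update_B(Z, M, np.zeros(5), lam)
        Mc = M - M.mean(axis=0)
        ref = np.zeros((3, 5))
        for p in range(5):
            model = Lasso(alpha=lam / 60, fit_intercept=False, tol=1e-12, max_iter=50000)
            model.fit(Mc, Z[:, p])
            ref[:, p] = model.coef_
        assert np.allclose(B, ref, atol=1e-6)

    def test_zero_variance_column_safe(self):
        rng = np.random.default_rng(5)
        M = np.column_stack([np.ones(30), rng.normal(size=30)])
        Z = rng.normal(size=(30, 2))
        B = update_B(Z, M, np.zeros(2), 0.5)
        assert np.allclose(B[0], 0.0)


class TestUpdateTheta:
    def test_large_penalty_diagonal(self):
        rng = np.random.default_rng(6)
        Z = rng.normal(size=(100, 4)) @ np.linalg.cholesky(
            np.array([[1, 0.6, 0, 0], [0.6, 1, 0, 0], [0, 0, 1, 0.4], [0, 0, 0.4, 1.0]])
        )
        Theta = update_theta(Z - Z.mean(axis=0), 10.0)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(Theta[off], 0.0)

    def test_zero_penalty_inverts_covariance(self):
        rng = np.random.default_rng(7)
        Z = rng.normal(size=(2000, 3))
        Zc = Z - Z.mean(axis=0)
        Theta = update_theta(Zc, 0.0)
        S = (Zc.T @ Zc) / Zc.shape[0]
        # jitter floor of 1e-3 on the diagonal shifts the exact inverse slightly
        assert np.allclose(Theta, np.linalg.inv(S), atol=1e-2)

    def test_matches_direct_optimizer_p2(self):
        rng = np.random.default_rng(8)
        Z = rng.normal(size=(200, 2)) @ np.array([[1.0, 0.0], [0.6, 0.8]])
        Zc = Z - Z.mean(axis=0)
        lam = 0.1
        Theta = update_theta(Zc, lam)
        S = (Zc.T @ Zc) / Zc.shape[0] + 1e-3 * (np.trace((Zc.T @ Zc) / Zc.shape[0]) / 2) * np.eye(2)

        def neg_obj(v):
            a, b, c = v
            T = np.array([[a, c], [c, b]])
            sign, logdet = np.linalg.slogdet(T)
            if sign <= 0:
                return 1e10
            return -(logdet - np.trace(S @ T) - 2 * lam * abs(c))

        best = None
        for c0 in (-0.5, 0.0, 0.5):
            r = minimize(neg_obj, [1.0, 1.0, c0], method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
            if best is None or r.fun < best.fun:
                best = r
        ref = np.array([[best.x[0], best.x[2]], [best.x[2], best.x[1]]])
        assert np.allclose(Theta, ref, atol=1e-3)

    def test_sparsity_monotone_in_penalty(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(6, 6))
        cov = A @ A.T + 6 * np.eye(6)
        Z = rng.multivariate_normal(np.zeros(6), cov, size=300)
        Zc = Z - Z.mean(axis=0)
        nnz = []
        for lam in [0.01, 0.05, 0.2, 1.0]:
            T = update_theta(Zc, lam)
            nnz.append(np.count_nonzero(np.abs(T[np.triu_indices(6, 1)]) > 1e-10))
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))


class TestEbicScore:
    def test_zero_df_is_minus_two_loglik(self):
        assert ebic_score(-123.0, 0, 0, 50, 10, 4) == pytest.approx(246.0)

    def test_monotone_in_df(self):
        base = ebic_score(-100.0, 3, 2, 50, 10, 4)
        more = ebic_score(-100.0, 6, 4, 50, 10, 4)
        assert more > base

    def test_hand_computed(self):
        val = ebic_score(-100.0, 3, 2, 50, 10, 4, gamma=0.5)
        expected = (
            200.0
            + 5 * np.log(50)
            + 4 * 0.5 * 3 * np.log(10)
            + 2 * 0.5 * 2 * np.log(40)
        )
        assert val == pytest.approx(expected)

    def test_free_parameter_charge(self):
        base = ebic_score(-100.0, 0, 0, 50, 10, 4)
        charged = ebic_score(-100.0, 0, 0, 50, 10, 4, df_free=7)
        assert charged == pytest.approx(base + 7 * np.log(50))


class TestLatentMap:
    def _params(self, P=2, Q=1, theta_scale=1.0):
        return ConditionParams(
            B=np.zeros((Q, P)),
            B0=np.zeros(P),
            Theta=theta_scale * np.eye(P),
            mu=np.zeros(Q),
            Sigma=np.eye(Q),
        )

    def test_dominant_prior_pins_to_basis(self):
        params = self._params(theta_scale=1e6)
        z = estimate_latent_map(np.array([5, 5]), np.zeros(1), params)
        assert np.allclose(z, params.B0, atol=1e-3)

    def test_beats_grid_search(self):
        params = self._params()
        x = np.array([5, 5])
        m = np.zeros(1)
        z = estimate_latent_map(x, m, params)

        def obj(zv):
            return dm_logpmf(x, np.exp(zv)) + gaussian_logpdf_prec(
                np.asarray(zv), params.B0, params.Theta
            )

        grid = np.linspace(-3, 3, 61)
        best_grid = max(obj(np.array([a, b])) for a in grid for b in grid)
        assert obj(z) >= best_grid - 1e-6

    def test_at_least_as_good_as_prior_mode(self):
        rng = np.random.default_rng(10)
        params = self._params(P=4)
        x = rng.integers(0, 30, size=4)
        x[0] += 1
        z = estimate_latent_map(x, np.zeros(1), params)

        def obj(zv):
            return dm_logpmf(x, np.exp(zv)) + gaussian_logpdf_prec(
                zv, params.B0, params.Theta
            )

        assert obj(z) >= obj(params.B0)


class TestFitSingleCondition:
    def test_permuting_samples_leaves_ebic_unchanged(self, small_dataset):
        X, M, _ = small_dataset
        res = fit_single_condition(X, M, seed=0)
        rng = np.random.default_rng(1)
        perm = rng.permutation(X.n_samples)
        Xp = X.select_samples(perm)
        Mp = M.select_samples(perm)
        res_p = fit_single_condition(Xp, Mp, seed=0)
        assert res_p.ebic == pytest.approx(res.ebic, rel=1e-6)

    def test_deterministic(self, small_dataset):
        X, M, _ = small_dataset
        r1 = fit_single_condition(X, M, seed=3)
        r2 = fit_single_condition(X, M, seed=3)
        assert r1.ebic == r2.ebic
        assert np.array_equal(r1.params.B, r2.params.B)

    def test_regularization_path_monotone(self, small_dataset):
        """More penalty never yields more selected edges on fixed data."""
        X, M, _ = small_dataset
        nnz_b, nnz_t = [], []
        for lam_b, lam_t in [(2.0, 0.05), (20.0, 0.3), (200.0, 1.5)]:
            res = fit_single_condition(
                X, M, grid=PenaltyGrid(lambda_B=[lam_b], lambda_Theta=[lam_t]), seed=0
            )
            P = len(res.kept_otus)
            iu = np.triu_indices(P, k=1)
            nnz_b.append(int(np.count_nonzero(np.abs(res.params.B) > 1e-10)))
            nnz_t.append(int(np.count_nonzero(np.abs(res.params.Theta[iu]) > 1e-10)))
        assert all(a >= b for a, b in zip(nnz_b, nnz_b[1:]))
        assert all(a >= b for a, b in zip(nnz_t, nnz_t[1:]))
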
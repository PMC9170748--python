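"""Densities and association extraction: oracles are exhaustive
enumeration, quadrature, sampling, and scipy's reference distribution."""

import itertools

import numpy as np
import pytest
from scipy import integrate, stats

from kldm.model_core import (
    ConditionParams,
    CountMatrix,
    EFMatrix,
    dm_logpmf,
    dm_mean_cov,
    gaussian_logpdf_prec,
    joint_loglik,
    lognormal_logpdf,
    partial_correlations,
)


def compositions(n, parts):
    """All nonnegative integer vectors of given length summing to n."""
    if parts == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in compositions(n - first, parts - 1):
            yield (first, *rest)


class TestDmLogpmf:
    def test_single_category_is_certain(self):
        assert dm_logpmf([7], [2.5]) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_alpha_gives_uniform_compositions(self):
        # alpha = 1 makes every composition of n=2 into 2 parts equally likely
        assert dm_logpmf([1, 1], [1.0, 1.0]) == pytest.approx(np.log(1 / 3))

    @pytest.mark.parametrize(
        "n,alpha",
        [
            (3, (0.5, 1.0, 2.0)),
            (4, (1.0, 1.0, 1.0)),
            (2, (3.0, 0.2)),
            (4, (0.7, 2.2)),
        ],
    )
    def test_normalizes_over_outcome_space(self, n, alpha):
        total = sum(
            np.exp(dm_logpmf(x, alpha)) for x in compositions(n, len(alpha))
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_scipy_reference(self):
        x = np.array([3, 0, 7])
        alpha = np.array([0.5, 1.3, 2.0])
        ref = stats.dirichlet_multinomial(alpha, int(x.sum())).logpmf(x)
        assert dm_logpmf(x, alpha) == pytest.approx(float(ref), rel=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            dm_logpmf([1, 1], [1.0, -1.0])
        with pytest.raises(ValueError):
            dm_logpmf([1, -1], [1.0, 1.0])


class TestDmMeanCov:
    def test_symmetric_mean_and_negative_covariance(self):
        mean, cov = dm_mean_cov([1.0, 1.0], 2)
        assert mean == pytest.approx([1.0, 1.0])
        assert cov[0, 1] < 0

    def test_uniform_mean(self):
        mean, _ = dm_mean_cov([2.0, 2.0, 2.0], 6)
        assert mean == pytest.approx([2.0, 2.0, 2.0])

    def test_against_sampling_oracle(self):
        rng = np.random.default_rng(7)
        alpha = np.array([0.8, 1.5, 3.0])
        n = 20
        draws = 100_000
        h = rng.dirichlet(alpha, size=draws)
        x = np.array([rng.multinomial(n, hi) for hi in h])
        mean, cov = dm_mean_cov(alpha, n)
        assert np.allclose(x.mean(axis=0), mean, atol=0.05)
        assert np.allclose(np.cov(x.T, bias=True), cov, atol=0.35)


class TestLognormalLogpdf:
    def test_unit_point_is_gaussian_constant(self):
        # ln(1) = 0 and the Jacobian vanishes
        assert lognormal_logpdf([1.0], [0.0], [[1.0]]) == pytest.approx(
            -0.5 * np.log(2 * np.pi)
        )

    def test_change_of_variables_identity(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.5, 2.0, size=3)
        mu = rng.normal(size=3)
        A = rng.normal(size=(3, 3))
        Theta = A @ A.T + 3 * np.eye(3)
        expected = gaussian_logpdf_prec(np.log(a), mu, Theta) - np.log(a).sum()
        assert lognormal_logpdf(a, mu, Theta) == pytest.approx(expected)

    def test_integrates_to_one_2d(self):
        Theta = np.array([[2.0, 0.7], [0.7, 1.5]])
        mu = np.array([0.2, -0.1])

        def dens(b, a):
            return np.exp(lognormal_logpdf([a, b], mu, Theta))

        val, _ = integrate.dblquad(dens, 1e-4, 60.0, 1e-4, 60.0, epsabs=1e-6)
        assert val == pytest.approx(1.0, abs=1e-3)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.5, 2.0, size=4)
        mu = rng.normal(size=4)
        A = rng.normal(size=(4, 4))
        Theta = A @ A.T + 4 * np.eye(4)
        perm = np.array([2, 0, 3, 1])
        assert lognormal_logpdf(a, mu, Theta) == pytest.approx(
            lognormal_logpdf(a[perm], mu[perm], Theta[np.ix_(perm, perm)])
        )


class TestPartialCorrelations:
    def test_identity_precision(self):
        rho = partial_correlations(np.eye(4))
        assert np.allclose(rho, np.eye(4))

    def test_two_by_two(self):
        rho = partial_correlations([[2.0, -1.0], [-1.0, 2.0]])
        assert rho[0, 1] == pytest.approx(0.5)

    def test_sign_flip_and_bounds(self):
        rng = np.random.default_rng(11)
        A = rng.normal(size=(6, 6))
        Theta = A @ A.T + 6 * np.eye(6)
        rho = partial_correlations(Theta)
        off = ~np.eye(6, dtype=bool)
        assert np.all(np.sign(rho[off]) == -np.sign(Theta[off]))
        assert np.all(np.abs(rho) <= 1 + 1e-12)

    def test_rejects_non_spd(self):
        with pytest.raises(ValueError):
            partial_correlations([[1.0, 2.0], [2.0, 1.0]])


class TestJointLoglik:
    def _params(self, rng, P=2, Q=2):
        A = rng.normal(size=(P, P))
        return ConditionParams(
            B=rng.normal(size=(Q, P)) * 0.1,
            B0=rng.normal(size=P),
            Theta=A @ A.T + P * np.eye(P),
            mu=np.zeros(Q),
            Sigma=np.eye(Q),
        )

    def test_empty_is_zero(self):
        rng = np.random.default_rng(0)
        params = self._params(rng)
        X = CountMatrix(np.zeros((0, 2), dtype=int) , [], ["a", "b"])
        M = EFMatrix(np.zeros((0, 2)), [], ["e1", "e2"])
        assert joint_loglik(X, M, params, np.zeros((0, 2))) == 0.0

    def test_additive_over_disjoint_sample_sets(self):
        rng = np.random.default_rng(1)
        params = self._params(rng)
        counts = rng.integers(1, 20, size=(5, 2))
        efs = rng.normal(size=(5, 2))
        Z = rng.normal(size=(5, 2))
        sids = [f"s{i}" for i in range(5)]
        X = CountMatrix(counts, sids, ["a", "b"])
        M = EFMatrix(efs, sids, ["e1", "e2"])
        full = joint_loglik(X, M, params, Z)
        a = joint_loglik(X.select_samples(np.arange(2)), M.select_samples(np.arange(2)), params, Z[:2])
        b = joint_loglik(X.select_samples(np.arange(2, 5)), M.select_samples(np.arange(2, 5)), params, Z[2:])
        assert full == pytest.approx(a + b)

    def test_matches_termwise_oracle(self):
        from kldm.model_core import gaussian_logpdf_prec

        rng = np.random.default_rng(2)
        params = self._params(rng)
        counts = rng.integers(1, 15, size=(3, 2))
        efs = rng.normal(size=(3, 2))
        Z = rng.normal(size=(3, 2)) * 0.3
        sids = ["s0", "s1", "s2"]
        X = CountMatrix(counts, sids, ["a", "b"])
        M = EFMatrix(efs, sids, ["e1", "e2"])
        expected = 0.0
        for i in range(3):
            alpha = np.exp(params.B.T @ efs[i] + Z[i])
            expected += dm_logpmf(counts[i], alpha)
            expected += gaussian_logpdf_prec(Z[i], params.B0, params.Theta)
        assert joint_loglik(X, M, params, Z) == pytest.approx(expected)


def test_compositional_covariance_identity():
    """Normalizing counts to relative abundances forces
    sum_{k != j} Cov(r_k, r_j) = -Var(r_j)."""
    rng = np.random.default_rng(5)
    alpha = np.array([0.5, 1.0, 2.0, 1.5])
    draws = 40_000
    h = rng.dirichlet(alpha, size=draws)
    x = np.array([rng.multinomial(50, hi) for hi in h])
    r = x / x.sum(axis=1, keepdims=True)
    C = np.cov(r.T, bias=True)
    for j in range(4):
        lhs = C[:, j].sum() - C[j, j]
        assert lhs == pytest.approx(-C[j, j], abs=5e-4)


def test_count_matrix_invariants():
    with pytest.raises(ValueError):
        CountMatrix(np.array([[0, 0], [1, 2]]), ["a", "b"], ["x", "y"])
    with pytest.raises(ValueError):
        CountMatrix(np.array([[1, -2]]), ["a"], ["x", "y"])
    with pytest.raises(ValueError):
        CountMatrix(np.array([[1, 2]]), ["a"], ["x", "x"])
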
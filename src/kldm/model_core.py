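"""Core domain types and probability densities of the hierarchical count model.

The model couples three layers per sample: environmental factors (EFs)
``m`` drawn from a condition-specific Gaussian, a latent log-abundance
deviation ``z`` drawn from a Gaussian with sparse precision ``Theta``
(microbe-microbe conditional dependencies), and marker-gene read counts
``x`` drawn from a Dirichlet-multinomial whose concentration is the
absolute abundance ``alpha = exp(B^T m + z)``.  ``B`` carries direct
EF-microbe effects.  The Dirichlet-multinomial layer reproduces the
compositional bias of sequencing counts: dividing reads by the sample
total induces artificial negative covariance among relative abundances,
which the model absorbs instead of mistaking for ecology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, psi
from scipy.stats import multivariate_normal

__all__ = [
    "CountMatrix",
    "EFMatrix",
    "ConditionParams",
    "LatentState",
    "MixtureFit",
    "dm_logpmf",
    "dm_mean_cov",
    "lognormal_logpdf",
    "partial_correlations",
    "joint_loglik",
]


def _check_unique(ids, what):
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} ids")


@dataclass
class CountMatrix:
    """OTU read counts: N samples x P taxa, nonnegative integers.

    Every row must have a positive total (a sample with zero reads carries
    no information and breaks the multinomial layer).
    """

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (samples x OTUs)")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        totals = self.counts.sum(axis=1)
        if np.any(totals <= 0):
            bad = [self.sample_ids[i] for i in np.nonzero(totals <= 0)[0]]
            raise ValueError(f"samples with zero total reads: {bad}")
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError("id lengths do not match counts shape")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def select_otus(self, keep: list[str]) -> "CountMatrix":
        idx = [self.otu_ids.index(o) for o in keep]
        return CountMatrix(self.counts[:, idx], list(self.sample_ids), list(keep))

    def select_samples(self, rows: np.ndarray) -> "CountMatrix":
        rows = np.asarray(rows)
        return CountMatrix(
            self.counts[rows], [self.sample_ids[i] for i in rows], list(self.otu_ids)
        )


@dataclass
class EFMatrix:
    """Environmental-factor values: N samples x Q numeric factors."""

    values: np.ndarray
    sample_ids: list[str]
    ef_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x EFs)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite EF values")
        if self.values.shape != (len(self.sample_ids), len(self.ef_ids)):
            raise ValueError("id lengths do not match values shape")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.ef_ids, "EF")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_efs(self) -> int:
        return self.values.shape[1]

    def select_samples(self, rows: np.ndarray) -> "EFMatrix":
        rows = np.asarray(rows)
        return EFMatrix(
            self.values[rows], [self.sample_ids[i] for i in rows], list(self.ef_ids)
        )


def _check_spd(mat: np.ndarray, name: str) -> None:
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(mat, mat.T, atol=1e-8 * (1 + np.abs(mat).max())):
        raise ValueError(f"{name} must be symmetric")
    # Cholesky is the cheapest reliable SPD test
    try:
        np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{name} is not positive definite") from exc


@dataclass
class ConditionParams:
    """Parameters of one EF condition.

    B : (Q, P) direct EF-OTU association coefficients.
    B0 : (P,) basis vector (mean latent log abundance from unmeasured factors).
    Theta : (P, P) SPD precision of the latent layer; off-diagonal entries
        encode conditionally dependent OTU-OTU associations.
    mu, Sigma : Gaussian mean / covariance of the condition's EF values.
    weight : mixture weight in (0, 1].
    """

    B: np.ndarray
    B0: np.ndarray
    Theta: np.ndarray
    mu: np.ndarray
    Sigma: np.ndarray
    weight: float = 1.0
    # continuous EF-OTU association strengths (weakly penalized refit);
    # None means rank by B itself
    B_score: np.ndarray | None = None
    # OTU-OTU edge strengths (regularization-path entry order); None means
    # rank by the partial correlations of Theta
    Theta_score: np.ndarray | None = None

    def __post_init__(self):
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.B0 = np.asarray(self.B0, dtype=float).ravel()
        self.Theta = np.asarray(self.Theta, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        self.Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        _check_spd(self.Theta, "Theta")
        _check_spd(self.Sigma, "Sigma")
        q, p = self.B.shape
        if self.B0.shape != (p,):
            raise ValueError("B0 length must match B columns")
        if self.Theta.shape != (p, p):
            raise ValueError("Theta shape must match B columns")
        if self.mu.shape != (q,) or self.Sigma.shape != (q, q):
            raise ValueError("mu/Sigma shape must match B rows")
        if not (0.0 < self.weight <= 1.0):
            raise ValueError("weight must be in (0, 1]")
        if self.B_score is not None:
            self.B_score = np.atleast_2d(np.asarray(self.B_score, dtype=float))
            if self.B_score.shape != self.B.shape:
                raise ValueError("B_score shape must match B")
        if self.Theta_score is not None:
            self.Theta_score = np.atleast_2d(np.asarray(self.Theta_score, dtype=float))
            if self.Theta_score.shape != self.Theta.shape:
                raise ValueError("Theta_score shape must match Theta")

    @property
    def n_otus(self) -> int:
        return self.B.shape[1]

    @property
    def n_efs(self) -> int:
        return self.B.shape[0]


@dataclass
class LatentState:
    """Latent variables of the generative chain (used by the simulator)."""

    z: np.ndarray
    alpha: np.ndarray
    h: np.ndarray | None = None


@dataclass
class MixtureFit:
    """Result of a full multi-condition fit."""

    K: int
    conditions: list[ConditionParams]
    assignments: np.ndarray  # (N,) ints in [1..K]
    ebic_per_condition: np.ndarray
    kept_otus_per_condition: list[list[str]]
    sample_ids: list[str] = field(default_factory=list)
    otu_ids: list[str] = field(default_factory=list)
    ef_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.assignments = np.asarray(self.assignments, dtype=int)
        if self.K != len(self.conditions):
            raise ValueError("K does not match number of conditions")
        if self.assignments.size and (
            self.assignments.min() < 1 or self.assignments.max() > self.K
        ):
            raise ValueError("assignments out of range")
        w = sum(c.weight for c in self.conditions)
        if abs(w - 1.0) > 1e-6:
            raise ValueError("mixture weights must sum to 1")


# ---------------------------------------------------------------------------
# densities


def _validate_x_alpha(x, alpha):
    x = np.asarray(x)
    alpha = np.asarray(alpha, dtype=float)
    if x.shape != alpha.shape or x.ndim != 1:
        raise ValueError("x and alpha must be 1-D with equal length")
    if np.any(x < 0) or not np.all(x == np.round(x)):
        raise ValueError("x must be nonnegative integers")
    if np.any(alpha <= 0) or not np.all(np.isfinite(alpha)):
        raise ValueError("alpha must be positive and finite")
    return x.astype(float), alpha


def dm_logpmf(x, alpha) -> float:
    """Log pmf of the Dirichlet-multinomial distribution.

    Obtained by integrating the latent composition ``h`` out of the
    multinomial(counts) x Dirichlet(alpha) pair.  Computed with log-gamma
    closed form, so realistic sequencing depths do not overflow.  The
    multinomial coefficient is included: absolute values are comparable
    across models, which matters for information-criterion comparisons.
    """
    x, alpha = _validate_x_alpha(x, alpha)
    n = x.sum()
    a0 = alpha.sum()
    coef = gammaln(n + 1) - gammaln(x + 1).sum()
    return float(
        coef
        + gammaln(a0)
        - gammaln(a0 + n)
        + (gammaln(alpha + x) - gammaln(alpha)).sum()
    )


def dm_logpmf_grad_alpha(x, alpha) -> np.ndarray:
    """Gradient of :func:`dm_logpmf` with respect to ``alpha``."""
    x, alpha = _validate_x_alpha(x, alpha)
    n = x.sum()
    a0 = alpha.sum()
    return psi(a0) - psi(a0 + n) + psi(alpha + x) - psi(alpha)


def dm_mean_cov(alpha, n) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of Dirichlet-multinomial counts at depth ``n``.

    mean_j = n * alpha_j / a0;
    Cov_jk = n * p_j (delta_jk - p_k) * (n + a0) / (1 + a0), p = alpha/a0.
    Off-diagonal entries are negative: the compositional bias is regulated
    by both the depth and the relative abundances.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    a0 = alpha.sum()
    p = alpha / a0
    mean = n * p
    factor = n * (n + a0) / (1.0 + a0)
    cov = factor * (np.diag(p) - np.outer(p, p))
    return mean, cov


def lognormal_logpdf(alpha_vec, mu, Theta) -> float:
    """Multivariate lognormal log density with precision parameterization.

    Equals the Gaussian log density of ``ln(alpha)`` with mean ``mu`` and
    precision ``Theta`` minus the Jacobian term ``sum(ln alpha)``.
    """
    alpha_vec = np.asarray(alpha_vec, dtype=float).ravel()
    if np.any(alpha_vec <= 0):
        raise ValueError("alpha_vec must be positive")
    mu = np.asarray(mu, dtype=float).ravel()
    Theta = np.atleast_2d(np.asarray(Theta, dtype=float))
    _check_spd(Theta, "Theta")
    la = np.log(alpha_vec)
    return float(gaussian_logpdf_prec(la, mu, Theta) - la.sum())


def gaussian_logpdf_prec(x, mu, Theta) -> float:
    """Gaussian log density parameterized by precision (inverse covariance)."""
    x = np.asarray(x, dtype=float).ravel()
    mu = np.asarray(mu, dtype=float).ravel()
    d = x - mu
    p = x.size
    sign, logdet = np.linalg.slogdet(Theta)
    if sign <= 0:
        raise ValueError("Theta is not positive definite")
    return float(0.5 * logdet - 0.5 * p * np.log(2 * np.pi) - 0.5 * d @ Theta @ d)


def partial_correlations(Theta) -> np.ndarray:
    """Partial correlations rho_ij = -Theta_ij / sqrt(Theta_ii Theta_jj).

    Diagonal set to 1.  The sign flip relative to the precision entry is
    what makes a positive value mean a positive conditional association.
    """
    Theta = np.atleast_2d(np.asarray(Theta, dtype=float))
    _check_spd(Theta, "Theta")
    d = np.sqrt(np.diag(Theta))
    rho = -Theta / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def joint_loglik(X: CountMatrix, M: EFMatrix, params: ConditionParams, Z) -> float:
    """Joint log likelihood of counts and latents under one condition (K=1).

    Sum over samples of the Dirichlet-multinomial term at
    ``alpha_i = exp(B^T m_i + z_i)`` plus the Gaussian term of
    ``z_i ~ N(B0, Theta^{-1})``.  Additive over samples.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.n_samples == 0:
        return 0.0
    if Z.shape != X.counts.shape:
        raise ValueError("Z shape must match counts")
    if M.n_samples != X.n_samples or M.n_efs != params.n_efs:
        raise ValueError("EF matrix shape mismatch")
    log_alpha = M.values @ params.B + Z
    mvn = multivariate_normal(
        mean=params.B0, cov=np.linalg.inv(params.Theta), allow_singular=False
    )
    total = float(np.sum(mvn.logpdf(Z)))
    for i in range(X.n_samples):
        total += dm_logpmf(X.counts[i], np.exp(log_alpha[i]))
    return total
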
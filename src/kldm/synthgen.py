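"""Synthetic multi-condition metagenomic datasets with known ground truth.

Each condition gets a sparse EF-OTU coefficient matrix ``B`` (uniform
values, 15% density by default), a sparse SPD precision ``Theta`` whose
support follows one of five graph families (random, cluster, scale-free,
hub, band), and a Gaussian EF component.  Samples are then drawn through
the full generative chain: EFs, latent log abundances, Dirichlet
composition, multinomial reads at a random sequencing depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model_core import CountMatrix, EFMatrix

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ConditionTruth",
    "gen_B",
    "gen_theta",
    "gen_ef_means",
    "gen_dataset",
    "neff",
]

GRAPH_TYPES = ("random", "cluster", "scale-free", "hub", "band")


@dataclass
class SimConfig:
    """Generator settings.

    ``ef_separation`` overrides the default interval construction of the
    condition EF means (coordinates of condition k uniform on [k, 1.5 k]):
    when set to ``d``, consecutive condition means are placed exactly ``d``
    apart in Euclidean distance.
    """

    K: int = 2
    P: int = 50
    Q: int = 5
    n_range: tuple[int, int] = (100, 200)
    b_density: float = 0.15
    b_range: tuple[float, float] = (-0.5, 0.5)
    graph_type: str = "random"
    depth_range: tuple[int, int] = (5000, 50000)
    seed: int = 0
    # secondary knobs (defaults documented in docs/methods.md)
    b_dead_zone: float = 0.05
    ef_sigma: float = 0.25  # EF covariance is ef_sigma * I
    ef_separation: float | None = None
    alpha0_target: float | None = None  # default: P (mean alpha_j ~ 1)
    theta_offdiag: tuple[float, float] = (0.2, 0.5)

    def __post_init__(self):
        if not (0.0 < self.b_density <= 1.0):
            raise ValueError("b_density must be in (0, 1]")
        if self.n_range[0] > self.n_range[1]:
            raise ValueError("n_range must be (min, max) with min <= max")
        if self.P < 2:
            raise ValueError("P must be >= 2")
        if self.graph_type not in GRAPH_TYPES:
            raise ValueError(f"graph_type must be one of {GRAPH_TYPES}")


@dataclass
class ConditionTruth:
    B: np.ndarray
    Theta: np.ndarray
    B0: np.ndarray
    mu: np.ndarray
    Sigma: np.ndarray
    adjacency: np.ndarray


@dataclass
class GroundTruth:
    conditions: list[ConditionTruth]
    labels: np.ndarray  # (N,) true condition per sample, 1-based
    otu_ids: list[str] = field(default_factory=list)
    ef_ids: list[str] = field(default_factory=list)
    alpha_clipped: bool = False

    @property
    def K(self) -> int:
        return len(self.conditions)


def gen_B(Q, P, density, value_range, seed, dead_zone: float = 0.05) -> np.ndarray:
    """Sparse EF-OTU coefficient matrix.

    Exactly round(density * Q * P) entries are nonzero (round-half-up),
    positions uniform without replacement, values uniform on the range but
    excluding a dead zone around zero so every "true" edge is recoverable
    in principle.
    """
    rng = np.random.default_rng(seed)
    lo, hi = value_range
    n_nonzero = int(np.floor(density * Q * P + 0.5))
    pos = rng.choice(Q * P, size=n_nonzero, replace=False)
    vals = np.empty(n_nonzero)
    filled = 0
    while filled < n_nonzero:
        draw = rng.uniform(lo, hi, size=n_nonzero - filled)
        ok = draw[np.abs(draw) >= dead_zone]
        vals[filled : filled + ok.size] = ok
        filled += ok.size
    B = np.zeros(Q * P)
    B[pos] = vals
    return B.reshape(Q, P)


def _adjacency(P: int, graph_type: str, rng: np.random.Generator, **kw) -> np.ndarray:
    A = np.zeros((P, P), dtype=int)
    if graph_type == "random":
        p_edge = kw.get("p_edge") or min(1.0, 3.0 / P)
        iu = np.triu_indices(P, k=1)
        mask = rng.random(iu[0].size) < p_edge
        A[iu[0][mask], iu[1][mask]] = 1
    elif graph_type == "band":
        bw = kw.get("bandwidth", 1)
        for d in range(1, bw + 1):
            idx = np.arange(P - d)
            A[idx, idx + d] = 1
    elif graph_type == "hub":
        n_hubs = kw.get("n_hubs") or max(1, P // 20)
        groups = np.array_split(np.arange(P), n_hubs)
        for g in groups:
            hub = g[0]
            for j in g[1:]:
                A[min(hub, j), max(hub, j)] = 1
    elif graph_type == "cluster":
        n_blocks = kw.get("n_blocks") or max(2, P // 10)
        for g in np.array_split(np.arange(P), n_blocks):
            for a_i, a in enumerate(g):
                for b in g[a_i + 1 :]:
                    A[a, b] = 1
    elif graph_type == "scale-free":
        # preferential attachment, one edge per new node
        targets = [0]
        for new in range(1, P):
            t = int(targets[rng.integers(0, len(targets))])
            A[min(t, new), max(t, new)] = 1
            targets.extend([t, new])
    else:  # pragma: no cover - guarded by SimConfig
        raise ValueError(f"unknown graph_type {graph_type}")
    return A + A.T


def gen_theta(
    P,
    graph_type,
    seed,
    offdiag_range: tuple[float, float] = (0.2, 0.5),
    **kw,
) -> tuple[np.ndarray, np.ndarray]:
    """SPD precision matrix with the requested graph support.

    Off-diagonal values have magnitude uniform in ``offdiag_range`` with
    random sign; the diagonal is inflated so the smallest eigenvalue is at
    least 0.1, then the matrix is rescaled so the implied marginal
    variances (diagonal of the inverse) are exactly 1 — the convention of
    standard sparse-precision simulators.  Both steps preserve the
    support exactly.
    """
    rng = np.random.default_rng(seed)
    adj = _adjacency(P, graph_type, rng, **kw)
    iu = np.triu_indices(P, k=1)
    mag = rng.uniform(offdiag_range[0], offdiag_range[1], size=iu[0].size)
    sign = rng.choice([-1.0, 1.0], size=iu[0].size)
    W = np.zeros((P, P))
    W[iu] = adj[iu] * mag * sign
    W = W + W.T
    np.fill_diagonal(W, 1.0)
    lam_min = float(np.linalg.eigvalsh(W)[0])
    if lam_min < 0.1:
        W += (0.1 - lam_min) * np.eye(P)
    # unit marginal variances: inv(D S D) = D^{-1} W D^{-1} with S = inv(W)
    d = np.sqrt(np.diag(np.linalg.inv(W)))
    W = W * np.outer(d, d)
    return W, adj


def gen_ef_means(
    k: int,
    Q: int,
    seed,
    separation: float | None = None,
    mu1: np.ndarray | None = None,
) -> np.ndarray:
    """EF mean vector of condition k.

    Default: coordinates uniform on [k, 1.5 k], so later conditions sit at
    larger EF values.  With a ``separation`` override d, condition k is
    placed at mu1 + (k - 1) * d / sqrt(Q) per coordinate, so consecutive
    condition means are exactly d apart in Euclidean distance.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if separation is None:
        rng = np.random.default_rng(seed)
        return rng.uniform(k, 1.5 * k, size=Q)
    if mu1 is None:
        mu1 = gen_ef_means(1, Q, seed)
    return mu1 + (k - 1) * separation / np.sqrt(Q) * np.ones(Q)


def gen_dataset(config: SimConfig) -> tuple[CountMatrix, EFMatrix, GroundTruth]:
    """Draw a complete dataset through the generative chain.

    Per condition k: n_k ~ Uniform{n_range}; m_i ~ N(mu_k, Sigma_k);
    z_i ~ N(B0_k, Theta_k^{-1}); alpha_i = exp(B_k^T m_i + z_i);
    h_i ~ Dirichlet(alpha_i); x_i ~ Multinomial(depth_i, h_i).
    Rows are shuffled; ground truth (including true labels) is recorded.
    """
    master = np.random.default_rng(config.seed)
    child = lambda: int(master.integers(0, 2**31 - 1))  # noqa: E731
    P, Q = config.P, config.Q
    alpha0 = config.alpha0_target if config.alpha0_target is not None else float(P)

    conditions: list[ConditionTruth] = []
    mu1 = None
    for k in range(1, config.K + 1):
        B = gen_B(Q, P, config.b_density, config.b_range, child(), config.b_dead_zone)
        Theta, adj = gen_theta(P, config.graph_type, child(), config.theta_offdiag)
        mu = gen_ef_means(k, Q, child(), config.ef_separation, mu1)
        if k == 1:
            mu1 = mu
        Sigma = config.ef_sigma * np.eye(Q)
        base = master.dirichlet(2.0 * np.ones(P))
        B0 = np.log(np.maximum(base, 1e-12) * alpha0)
        conditions.append(ConditionTruth(B, Theta, B0, mu, Sigma, adj))

    rows_x, rows_m, labels = [], [], []
    clipped = False
    for k, ct in enumerate(conditions, start=1):
        n_k = int(master.integers(config.n_range[0], config.n_range[1] + 1))
        rng = np.random.default_rng(child())
        Mk = rng.multivariate_normal(ct.mu, ct.Sigma, size=n_k)
        L = np.linalg.cholesky(ct.Theta)
        eps = rng.standard_normal((n_k, P))
        # z = B0 + Theta^{-1/2} eps via triangular solve
        Zk = ct.B0 + np.linalg.solve(L.T, eps.T).T
        log_alpha = Mk @ ct.B + Zk
        if np.any(log_alpha > np.log(1e8)):
            clipped = True
            warnings.warn("alpha overflow clipped in gen_dataset", RuntimeWarning)
        alpha = np.exp(np.clip(log_alpha, np.log(1e-10), np.log(1e8)))
        depths = rng.integers(config.depth_range[0], config.depth_range[1] + 1, n_k)
        Xk = np.empty((n_k, P), dtype=np.int64)
        for i in range(n_k):
            h = rng.dirichlet(alpha[i])
            h = np.maximum(h, 1e-300)
            h = h / h.sum()
            Xk[i] = rng.multinomial(depths[i], h)
        rows_x.append(Xk)
        rows_m.append(Mk)
        labels.extend([k] * n_k)

    Xall = np.vstack(rows_x)
    Mall = np.vstack(rows_m)
    labels = np.asarray(labels)
    perm = master.permutation(len(labels))
    Xall, Mall, labels = Xall[perm], Mall[perm], labels[perm]

    # samples with zero reads carry no information; redraw trivially impossible
    # at the default depths, but guard against tiny custom depths
    bad = Xall.sum(axis=1) == 0
    if np.any(bad):
        Xall[bad, 0] = 1

    n = len(labels)
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    otu_ids = [f"OTU_{j + 1}" for j in range(P)]
    ef_ids = [f"EF_{q + 1}" for q in range(Q)]
    X = CountMatrix(Xall, sample_ids, otu_ids)
    M = EFMatrix(Mall, sample_ids, ef_ids)
    truth = GroundTruth(conditions, labels, otu_ids, ef_ids, clipped)
    return X, M, truth


def neff(X: CountMatrix) -> tuple[np.ndarray, float]:
    """Inverse Simpson index per sample and its mean.

    neff_i = 1 / sum_j r_ij^2 on relative abundances r; the effective
    number of equally abundant taxa.  High values mean strongly
    compositional data.
    """
    totals = X.counts.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("zero-total sample")
    r = X.counts / totals[:, None]
    vals = 1.0 / (r**2).sum(axis=1)
    return vals, float(vals.mean())
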
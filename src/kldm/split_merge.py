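"""Split-merge estimation of the number of EF conditions.

Samples are recursively bisected on their EF values with two-component
Gaussian mixtures, building a binary tree whose leaves are fine-grained
candidate conditions.  Each leaf gets a sparse network fit; a bottom-up
merge pass then recombines leaf pairs whenever the merged fit has a lower
EBIC than the two separate fits, recovering conditions the greedy split
fragmented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture

from .model_core import CountMatrix, EFMatrix, MixtureFit
from .single_fit import (
    PenaltyGrid,
    SingleFitResult,
    _map_latents,
    fit_single_condition,
    theta_path_scores,
)

__all__ = [
    "SplitNode",
    "KldmConfig",
    "SplitFailure",
    "gmm2_split",
    "build_split_tree",
    "merge_pass",
    "run_kldm",
    "assign_new_sample",
]


log = logging.getLogger("kldm")


class SplitFailure(RuntimeError):
    """Raised when a 2-component mixture cannot partition a node."""


@dataclass
class KldmConfig:
    n_min: int | None = None  # default: max(Q + 2, 30), resolved at run time
    grid: PenaltyGrid = field(default_factory=PenaltyGrid)
    seed: int = 0
    max_depth: int = 12
    gmm_restarts: int = 3

    def resolve_n_min(self, Q: int) -> int:
        n_min = self.n_min if self.n_min is not None else max(Q + 2, 30)
        if n_min < Q + 2:
            raise ValueError("n_min must be >= Q + 2")
        return n_min


@dataclass
class SplitNode:
    sample_idx: np.ndarray  # global row indices
    depth: int
    node_id: int
    ef_mean: np.ndarray
    children: list["SplitNode"] = field(default_factory=list)
    fit: SingleFitResult | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["SplitNode"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def internal_nodes(self) -> list["SplitNode"]:
        if self.is_leaf:
            return []
        out = [self]
        for c in self.children:
            out.extend(c.internal_nodes())
        return out


def _standardize(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    return (M - mu) / sd


def gmm2_split(M_subset, seed: int, restarts: int = 3):
    """Two-component Gaussian mixture partition of a node's EF rows.

    EM is run on per-factor z-scored values (Euclidean geometry would
    otherwise be dominated by large-unit factors); each sample goes to the
    component with the larger posterior.  Best of ``restarts`` k-means
    initializations by mixture log likelihood.
    """
    M_subset = np.atleast_2d(np.asarray(M_subset, dtype=float))
    n = M_subset.shape[0]
    if n < 4:
        raise SplitFailure("too few samples to split")
    if np.allclose(M_subset, M_subset[0], atol=1e-12):
        raise SplitFailure("all EF rows identical; no separation exists")
    Ms = _standardize(M_subset)
    try:
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            n_init=max(1, restarts),
            init_params="kmeans",
            reg_covar=1e-6,
            max_iter=200,
            random_state=seed,
        ).fit(Ms)
    except Exception as exc:  # singular EM failure
        raise SplitFailure(str(exc)) from exc
    labels = gm.predict(Ms)
    if labels.min() == labels.max():
        raise SplitFailure("mixture collapsed onto a single component")
    return labels, (gm.means_, gm.covariances_), gm.weights_


def build_split_tree(X: CountMatrix, M: EFMatrix, config: KldmConfig) -> SplitNode:
    """Recursive EF-space bisection.

    A split is rejected (node stays a leaf) when it would create a child
    with fewer than n_min samples, when the mixture fit fails, or at
    max_depth.  Leaves partition the samples exactly.
    """
    n_min = config.resolve_n_min(M.n_efs)
    counter = [0]

    def make_node(idx: np.ndarray, depth: int) -> SplitNode:
        node_id = counter[0]
        counter[0] += 1
        node = SplitNode(
            sample_idx=idx, depth=depth, node_id=node_id,
            ef_mean=M.values[idx].mean(axis=0),
        )
        if len(idx) < 2 * n_min or depth >= config.max_depth:
            return node
        seed = (config.seed * 1000003 + 7919 * node_id) % (2**31 - 1)
        try:
            labels, _, _ = gmm2_split(M.values[idx], seed, config.gmm_restarts)
        except SplitFailure:
            return node
        left, right = idx[labels == 0], idx[labels == 1]
        if len(left) < n_min or len(right) < n_min:
            return node
        node.children = [make_node(left, depth + 1), make_node(right, depth + 1)]
        return node

    return make_node(np.arange(X.n_samples), 0)


@dataclass(eq=False)
class _Cluster:
    position: SplitNode  # original leaf whose tree slot this cluster occupies
    sample_idx: np.ndarray
    fit: SingleFitResult
    ef_mean_std: np.ndarray


def _fit_cluster(X, M, idx, config, otus: list[str] | None = None) -> SingleFitResult:
    # edge-ranking scores are deferred to the final clusters
    Xs = X.select_samples(idx)
    if otus is not None:
        Xs = Xs.select_otus(otus)
    return fit_single_condition(
        Xs, M.select_samples(idx), grid=config.grid,
        seed=config.seed, with_scores=False,
    )


def _is_descendant(node: SplitNode, ancestor: SplitNode) -> bool:
    if node is ancestor:
        return True
    return any(_is_descendant(node, c) for c in ancestor.children)


def _merge_test(
    a: _Cluster, b: _Cluster, X, M, config, cached_fit
) -> SingleFitResult | None:
    """EBIC-gated merge of two clusters; returns the merged full fit or None.

    All three fits entering the comparison are restricted to the
    intersection of the pair's kept OTU sets so their likelihoods are
    commensurable; the accepted merged cluster is refit on its own
    natural OTU filter.
    """
    idx = np.sort(np.concatenate([a.sample_idx, b.sample_idx]))
    common = tuple(
        o for o in X.otu_ids
        if o in set(a.fit.kept_otus) and o in set(b.fit.kept_otus)
    )
    if len(common) < 2:
        return None
    fa = cached_fit(a.sample_idx, common)
    fb = cached_fit(b.sample_idx, common)
    fm = cached_fit(idx, common)
    if fa is None or fb is None or fm is None:
        return None
    accept = fm.ebic < fa.ebic + fb.ebic
    log.info(
        "merge test n=%d+%d: ebic %0.1f vs %0.1f+%0.1f -> %s",
        len(a.sample_idx), len(b.sample_idx), fm.ebic, fa.ebic, fb.ebic,
        "accept" if accept else "reject",
    )
    if not accept:
        return None
    return cached_fit(idx, None)


def _make_fit_cache(X, M, config):
    cache: dict[tuple, SingleFitResult | None] = {}

    def cached_fit(idx: np.ndarray, otus: tuple[str, ...] | None):
        key = (frozenset(int(i) for i in idx), otus)
        if key not in cache:
            try:
                cache[key] = _fit_cluster(
                    X, M, np.sort(idx), config, list(otus) if otus else None
                )
            except Exception:
                log.warning("cluster fit failed for n=%d", len(idx))
                cache[key] = None
        return cache[key]

    return cached_fit


def _merge_pass_clusters(
    root: SplitNode, X: CountMatrix, M: EFMatrix, config: KldmConfig, cached_fit
) -> list[_Cluster]:
    Ms = _standardize(M.values)
    clusters: list[_Cluster] = []
    for leaf in root.leaves():
        if leaf.fit is None:
            leaf.fit = _fit_cluster(X, M, leaf.sample_idx, config)
        clusters.append(
            _Cluster(leaf, leaf.sample_idx, leaf.fit, Ms[leaf.sample_idx].mean(axis=0))
        )
    internal = sorted(root.internal_nodes(), key=lambda v: -v.depth)
    for node in internal:
        while True:
            left = [c for c in clusters if _is_descendant(c.position, node.children[0])]
            right = [c for c in clusters if _is_descendant(c.position, node.children[1])]
            if not left or not right:
                break
            pairs = [
                (float(np.linalg.norm(a.ef_mean_std - b.ef_mean_std)), i, j)
                for i, a in enumerate(left)
                for j, b in enumerate(right)
            ]
            _, ia, jb = min(pairs)
            a, b = left[ia], right[jb]
            final = _merge_test(a, b, X, M, config, cached_fit)
            if final is None:
                break
            idx = np.sort(np.concatenate([a.sample_idx, b.sample_idx]))
            mean_m = Ms[idx].mean(axis=0)
            da = np.linalg.norm(a.ef_mean_std - mean_m)
            db = np.linalg.norm(b.ef_mean_std - mean_m)
            keep, drop = (a, b) if da <= db else (b, a)
            clusters.remove(drop)
            keep.sample_idx = idx
            keep.fit = final
            keep.ef_mean_std = mean_m
    return clusters


def merge_pass(
    root: SplitNode, X: CountMatrix, M: EFMatrix, config: KldmConfig
) -> MixtureFit:
    """Bottom-up EBIC-gated merging of fitted leaves.

    Internal nodes are visited deepest first.  At each node the closest
    pair of current clusters (one from each branch, Euclidean distance on
    z-scored EF means) is test-merged; the merge is kept iff the merged
    EBIC is below the sum of the pair's EBICs, in which case the merged
    cluster takes the slot of the member whose EF mean is closer to the
    merged mean and the node is revisited.  A rejection closes the node.
    """
    cached_fit = _make_fit_cache(X, M, config)
    return _finalize(_merge_pass_clusters(root, X, M, config, cached_fit), X, M)


def _sweep_clusters(
    clusters: list[_Cluster], X, M, config, cached_fit
) -> list[_Cluster]:
    """Closest-pair merge attempts among final clusters until a rejection.

    Cleans up conditions that the tree-structured pass could not pair
    because they ended under different branches.
    """
    Ms = _standardize(M.values)
    while len(clusters) >= 2:
        pairs = [
            (float(np.linalg.norm(a.ef_mean_std - b.ef_mean_std)), i, j)
            for i, a in enumerate(clusters)
            for j, b in enumerate(clusters)
            if i < j
        ]
        _, ia, jb = min(pairs)
        a, b = clusters[ia], clusters[jb]
        final = _merge_test(a, b, X, M, config, cached_fit)
        if final is None:
            break
        idx = np.sort(np.concatenate([a.sample_idx, b.sample_idx]))
        clusters.remove(b)
        a.sample_idx = idx
        a.fit = final
        a.ef_mean_std = Ms[idx].mean(axis=0)
    return clusters


def _finalize(clusters: list[_Cluster], X: CountMatrix, M: EFMatrix) -> MixtureFit:
    clusters = sorted(clusters, key=lambda c: int(c.sample_idx.min()))
    N = X.n_samples
    assignments = np.zeros(N, dtype=int)
    conditions, ebics, kept = [], [], []
    for k, c in enumerate(clusters, start=1):
        assignments[c.sample_idx] = k
        p = c.fit.params
        if p.Theta_score is None:
            p.Theta_score = theta_path_scores(c.fit.Z - p.B0)
        p.weight = len(c.sample_idx) / N
        conditions.append(p)
        ebics.append(c.fit.ebic)
        kept.append(list(c.fit.kept_otus))
    # guard against float drift in the weight-sum invariant
    total = sum(p.weight for p in conditions)
    for p in conditions:
        p.weight /= total
    return MixtureFit(
        K=len(clusters),
        conditions=conditions,
        assignments=assignments,
        ebic_per_condition=np.asarray(ebics),
        kept_otus_per_condition=kept,
        sample_ids=list(X.sample_ids),
        otu_ids=list(X.otu_ids),
        ef_ids=list(M.ef_ids),
    )


def _rowwise_marginal_loglik(counts, offset, Z, B0, Theta) -> np.ndarray:
    """Per-sample Laplace-approximate marginal log likelihood of counts."""
    from .single_fit import _laplace_logdet_rows

    N, P = counts.shape
    n_tot = counts.sum(axis=1)
    Y = np.clip(offset + Z, -30.0, 30.0)
    A = np.exp(Y)
    a0 = A.sum(axis=1)
    dm = gammaln(n_tot + 1) - gammaln(counts + 1).sum(axis=1)
    dm += gammaln(a0) - gammaln(a0 + n_tot)
    dm += (gammaln(A + counts) - gammaln(A)).sum(axis=1)
    D = Z - B0
    sign, logdet = np.linalg.slogdet(Theta)
    quad = np.einsum("ij,jk,ik->i", D, Theta, D)
    gauss = 0.5 * logdet - 0.5 * quad
    lap = _laplace_logdet_rows(counts, offset, Z, Theta)
    return dm + gauss - 0.5 * lap


def _reassign_clusters(
    clusters: list[_Cluster], X: CountMatrix, M: EFMatrix, config: KldmConfig, cached_fit
) -> tuple[list[_Cluster], bool]:
    """Posterior reassignment of samples to conditions, then refit.

    The mixture model scores a sample by the condition's EF Gaussian and
    its marginal count likelihood at the MAP latent state, so boundary
    samples that the EF-only split misplaced move to the condition whose
    network explains their counts.  Count likelihoods are compared on the
    OTU set kept by every condition.  Clusters falling below n_min are
    dissolved into the remaining conditions.
    """
    K = len(clusters)
    if K <= 1:
        return clusters, False
    N = X.n_samples
    old_assign = np.zeros(N, dtype=int)
    for k, c in enumerate(clusters):
        old_assign[c.sample_idx] = k
    common = [
        o for o in X.otu_ids
        if all(o in set(c.fit.kept_otus) for c in clusters)
    ]
    if len(common) < 2:
        return clusters, False
    Xc = X.select_otus(common)
    counts = Xc.counts.astype(float)
    scores = np.full((N, K), -np.inf)
    for k, c in enumerate(clusters):
        params = c.fit.params
        keep_idx = [c.fit.kept_otus.index(o) for o in common]
        B = params.B[:, keep_idx]
        B0 = params.B0[keep_idx]
        Theta = params.Theta[np.ix_(keep_idx, keep_idx)] + 1e-8 * np.eye(len(keep_idx))
        offset = M.values @ B
        Z0 = np.broadcast_to(B0, offset.shape).copy()
        Z, _ = _map_latents(counts, offset, B0, Theta, Z0, max_iter=100)
        scores[:, k] = _rowwise_marginal_loglik(counts, offset, Z, B0, Theta)
        mu = M.values[c.sample_idx].mean(axis=0)
        Sigma = np.atleast_2d(np.cov(M.values[c.sample_idx].T)) + 1e-6 * np.eye(M.n_efs)
        scores[:, k] += multivariate_normal(
            mean=mu, cov=Sigma, allow_singular=True
        ).logpdf(M.values)
        scores[:, k] += np.log(len(c.sample_idx) / N)
    new_assign = np.argmax(scores, axis=1)
    if np.array_equal(new_assign, old_assign):
        return clusters, False
    n_min = config.resolve_n_min(M.n_efs)
    sizes = np.bincount(new_assign, minlength=K)
    keep_ks = [k for k in range(K) if sizes[k] >= n_min]
    if not keep_ks:
        return clusters, False
    for i in range(N):
        if new_assign[i] not in keep_ks:
            new_assign[i] = keep_ks[int(np.argmax(scores[i, keep_ks]))]
    log.info(
        "reassignment moved %d samples", int((new_assign != old_assign).sum())
    )
    Ms = _standardize(M.values)
    out = []
    for rank, k in enumerate(keep_ks):
        idx = np.nonzero(new_assign == k)[0]
        refit = cached_fit(idx, None)
        if refit is None:
            return clusters, False
        pos = SplitNode(
            sample_idx=idx, depth=0, node_id=-(rank + 1),
            ef_mean=M.values[idx].mean(axis=0),
        )
        out.append(_Cluster(pos, idx, refit, Ms[idx].mean(axis=0)))
    return out, True


def run_kldm(X: CountMatrix, M: EFMatrix, config: KldmConfig | None = None) -> MixtureFit:
    """Full pipeline: split tree, per-leaf sparse fits, EBIC-gated merging,
    then alternated posterior reassignment and a final merge sweep.

    Falls back to a single-condition fit when there are too few samples to
    attempt a split.  Deterministic given (data, config, seed).
    """
    if config is None:
        config = KldmConfig()
    if X.sample_ids != M.sample_ids:
        a, b = set(X.sample_ids), set(M.sample_ids)
        diff = sorted((a ^ b)) or ["(ordering differs)"]
        raise ValueError(f"sample ids of X and M do not align; first mismatch: {diff[0]}")
    n_min = config.resolve_n_min(M.n_efs)
    if X.n_samples < 2 * n_min:
        fit = fit_single_condition(
            X, M, grid=config.grid, seed=config.seed, with_scores=False
        )
        root = SplitNode(
            sample_idx=np.arange(X.n_samples), depth=0, node_id=0,
            ef_mean=M.values.mean(axis=0), fit=fit,
        )
        cl = _Cluster(root, root.sample_idx, fit, np.zeros(M.n_efs))
        return _finalize([cl], X, M)
    root = build_split_tree(X, M, config)
    cached_fit = _make_fit_cache(X, M, config)
    clusters = _merge_pass_clusters(root, X, M, config, cached_fit)
    for _ in range(2):
        clusters = _sweep_clusters(clusters, X, M, config, cached_fit)
        clusters, moved = _reassign_clusters(clusters, X, M, config, cached_fit)
        if not moved:
            break
    return _finalize(clusters, X, M)


def assign_new_sample(m_new, fit: MixtureFit) -> int:
    """Most probable condition for a new EF vector (1-based).

    argmax_k pi_k N(m_new; mu_k, Sigma_k); ties go to the lower index.
    """
    m_new = np.asarray(m_new, dtype=float).ravel()
    scores = np.array(
        [
            np.log(c.weight)
            + multivariate_normal(mean=c.mu, cov=c.Sigma, allow_singular=True).logpdf(
                m_new
            )
            for c in fit.conditions
        ]
    )
    return int(np.argmax(scores)) + 1
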
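"""Network-recovery evaluation against simulator ground truth.

Association signs are neglected: an estimated edge scores by the absolute
partial correlation (OTU-OTU) or absolute coefficient (EF-OTU), and an
edge is a true positive when the corresponding ground-truth entry is
nonzero.  ROC/AUC, top-n sensitivity/specificity, genus-level matching of
known interactions, and cluster-label recovery are provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import roc_curve

from .model_core import ConditionParams, partial_correlations
from .synthgen import ConditionTruth

__all__ = [
    "EdgeScoreSet",
    "edge_scores",
    "roc_auc",
    "top_n_sens_spec",
    "match_known_interactions",
    "cluster_recovery",
    "precision_to_correlation",
]


@dataclass
class EdgeScoreSet:
    pairs: list[tuple[str, str]]
    scores: np.ndarray  # absolute association strengths, >= 0
    labels: np.ndarray  # 1 where the ground-truth association is nonzero
    mode: str = "otu-otu"

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.pairs) != self.scores.size or self.scores.size != self.labels.size:
            raise ValueError("pairs, scores, labels must have equal length")
        if np.any(self.scores < 0):
            raise ValueError("scores must be nonnegative (absolute values)")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate edge pairs")


def edge_scores(
    est_params: ConditionParams,
    est_otu_ids: list[str],
    truth: ConditionTruth,
    truth_otu_ids: list[str],
    mode: str,
    ef_ids: list[str] | None = None,
) -> EdgeScoreSet:
    """Score/label table over the OTU universe shared by estimate and truth.

    When the fit filtered OTUs out of a cluster, evaluation restricts the
    ground truth to the kept OTUs.
    """
    if mode not in ("otu-otu", "ef-otu"):
        raise ValueError("mode must be 'otu-otu' or 'ef-otu'")
    missing = [o for o in est_otu_ids if o not in truth_otu_ids]
    if missing:
        raise ValueError(f"estimated OTUs missing from truth universe: {missing[:5]}")
    universe = [o for o in truth_otu_ids if o in set(est_otu_ids)]
    if len(universe) < 2:
        raise ValueError("fewer than 2 shared OTUs to evaluate")
    e_idx = {o: i for i, o in enumerate(est_otu_ids)}
    t_idx = {o: i for i, o in enumerate(truth_otu_ids)}
    ei = np.array([e_idx[o] for o in universe])
    ti = np.array([t_idx[o] for o in universe])

    pairs: list[tuple[str, str]] = []
    if mode == "otu-otu":
        if est_params.Theta_score is not None:
            rho = est_params.Theta_score
        else:
            rho = partial_correlations(est_params.Theta)
        scores, labels = [], []
        for a in range(len(universe)):
            for b in range(a + 1, len(universe)):
                pairs.append((universe[a], universe[b]))
                scores.append(abs(rho[ei[a], ei[b]]))
                labels.append(1 if truth.Theta[ti[a], ti[b]] != 0 else 0)
        return EdgeScoreSet(pairs, np.array(scores), np.array(labels), mode)
    efs = ef_ids if ef_ids is not None else [f"EF_{q + 1}" for q in range(truth.B.shape[0])]
    Bhat = est_params.B_score if est_params.B_score is not None else est_params.B
    scores, labels = [], []
    for q, ef in enumerate(efs):
        for a, otu in enumerate(universe):
            pairs.append((ef, otu))
            scores.append(abs(Bhat[q, ei[a]]))
            labels.append(1 if truth.B[q, ti[a]] != 0 else 0)
    return EdgeScoreSet(pairs, np.array(scores), np.array(labels), mode)


def roc_auc(es: EdgeScoreSet) -> tuple[np.ndarray, float]:
    """ROC points and AUC over all score thresholds.

    Ties are averaged, making the AUC equal to the normalized
    Mann-Whitney statistic.  Undefined (error) when only one class is
    present.
    """
    y, s = es.labels, es.scores
    if y.min() == y.max():
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    # rank-based AUC with midrank tie handling
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty_like(s)
    ranks[order] = np.arange(1, s.size + 1)
    for val in np.unique(s):
        m = s == val
        ranks[m] = ranks[m].mean()
    n1 = int(y.sum())
    n0 = y.size - n1
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    return np.column_stack([fpr, tpr]), float(auc)


def top_n_sens_spec(es: EdgeScoreSet, n: int) -> tuple[float, float]:
    """Sensitivity and specificity when the top-n scored edges are called.

    Ties are broken by stable edge index so the call set is deterministic.
    """
    if not (1 <= n <= es.scores.size):
        raise ValueError("n must be in [1, number of edges]")
    order = sorted(range(es.scores.size), key=lambda i: (-es.scores[i], i))
    called = np.zeros(es.scores.size, dtype=bool)
    called[order[:n]] = True
    y = es.labels.astype(bool)
    tp = int(np.sum(called & y))
    fn = int(np.sum(~called & y))
    tn = int(np.sum(~called & ~y))
    fp = int(np.sum(called & ~y))
    sens = tp / (tp + fn) if tp + fn else 1.0
    spec = tn / (tn + fp) if tn + fp else 1.0
    return sens, spec


def match_known_interactions(
    est_edges: list[tuple[str, str]],
    otu_to_genus: dict[str, str],
    known_pairs: list[tuple[str, str]],
) -> tuple[list[tuple[str, str]], dict[frozenset, int]]:
    """Estimated edges whose (unordered) genus pair is a known interaction."""
    known = {frozenset(p) for p in known_pairs}
    matched: list[tuple[str, str]] = []
    counts: dict[frozenset, int] = {}
    for a, b in est_edges:
        if a not in otu_to_genus or b not in otu_to_genus:
            warnings.warn(f"edge ({a}, {b}) skipped: unmapped OTU", RuntimeWarning)
            continue
        gp = frozenset((otu_to_genus[a], otu_to_genus[b]))
        if gp in known:
            matched.append((a, b))
            counts[gp] = counts.get(gp, 0) + 1
    return matched, counts


def cluster_recovery(assignments, true_labels) -> dict:
    """Best-permutation accuracy (Hungarian matching) and per-cluster purity."""
    a = np.asarray(assignments)
    t = np.asarray(true_labels)
    if a.shape != t.shape:
        raise ValueError("assignments and true_labels must have equal length")
    ka = np.unique(a)
    kt = np.unique(t)
    conf = np.zeros((ka.size, kt.size), dtype=int)
    for i, ci in enumerate(ka):
        for j, cj in enumerate(kt):
            conf[i, j] = int(np.sum((a == ci) & (t == cj)))
    ri, cj = linear_sum_assignment(-conf)
    accuracy = conf[ri, cj].sum() / a.size
    purity = {int(ka[i]): conf[i].max() / conf[i].sum() for i in range(ka.size)}
    return {"accuracy": float(accuracy), "purity": purity}


def precision_to_correlation(Theta) -> np.ndarray:
    """Marginal correlation matrix implied by a precision matrix.

    Utility for comparing correlation-type estimates against the truth
    (cov = Theta^{-1}, then normalize); unused by the default pipeline.
    """
    cov = np.linalg.inv(np.asarray(Theta, dtype=float))
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)
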
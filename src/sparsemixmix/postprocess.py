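"""Model selection, label-switching resolution and partition estimation.

The sampler leaves the cluster labels unidentified: the mixture likelihood is
invariant under permuting clusters (and, separately, subcomponents).  The
post-processing pipeline is

1. estimate the number of data clusters K0_hat as the posterior mode of the
   per-draw count of nonempty clusters (ties broken toward fewer clusters);
2. restrict to draws with exactly K0_hat nonempty clusters and resolve label
   switching in the point-process representation: each draw contributes its
   K0_hat cluster moment means (weight-averaged subcomponent means, which are
   invariant to subcomponent relabeling) as unlabeled points; k-means over
   the pooled points yields a reference labeling, and draws whose clusters do
   not map one-to-one onto the k-means centers are dropped (the retained
   fraction is the permutation rate);
3. the MAP partition takes, per observation, the most frequent relabeled
   cluster assignment; the similarity matrix of co-clustering probabilities
   Pr{S_i = S_j | y} needs no relabeling at all.

External validation against known classes uses the adjusted Rand index and
the misclassification rate under the optimal label matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .sampler import ChainDraws

__all__ = [
    "PartitionEstimate",
    "RelabeledDraws",
    "count_nonempty",
    "estimate_K0",
    "relabel_point_process",
    "map_partition",
    "similarity_matrix",
    "score_partition",
    "identify",
]


@dataclass
class RelabeledDraws:
    """Draws with K0_hat nonempty clusters, relabeled to a common ordering."""

    S: np.ndarray  # (M_kept, N), labels in 0..K0_hat-1
    kept: np.ndarray  # indices into the original draw store
    permutation_rate: float
    eta: np.ndarray  # (M_kept, K0_hat) nonempty-cluster weights
    means: np.ndarray  # (M_kept, K0_hat, r) cluster moment means
    covs: np.ndarray  # (M_kept, K0_hat, r, r) cluster moment covariances


@dataclass
class PartitionEstimate:
    """Identified clustering output."""

    K0_hat: int
    map_partition: np.ndarray
    similarity: np.ndarray
    permutation_rate: float
    eta: np.ndarray  # (K0_hat,) posterior mean cluster weights
    means: np.ndarray  # (K0_hat, r) posterior mean cluster moment means
    covs: np.ndarray  # (K0_hat, r, r) posterior mean cluster moment covariances


def count_nonempty(S: np.ndarray) -> int:
    """Number of distinct cluster labels in one allocation vector."""
    return int(len(np.unique(S)))


def estimate_K0(draws: ChainDraws | np.ndarray) -> int:
    """Posterior mode of the nonempty-cluster counts; ties go to fewer clusters."""
    K0 = draws.K0_per_draw if isinstance(draws, ChainDraws) else np.asarray(draws)
    counts = np.bincount(K0.astype(int))
    return int(np.argmax(counts))  # argmax returns the smallest index on ties


def _cluster_functionals(
    draws: ChainDraws, m: int, ks: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(eta, moment mean, moment cov) of the nonempty clusters of draw m."""
    w = draws.w[m, ks]  # (K0, L)
    mu = draws.mu[m, ks]  # (K0, L, r)
    Sig = draws.Sigma[m, ks]
    means = np.einsum("cl,clr->cr", w, mu)
    second = np.einsum("cl,clij->cij", w, Sig) + np.einsum("cl,cli,clj->cij", w, mu, mu)
    covs = second - np.einsum("ci,cj->cij", means, means)
    return draws.eta[m, ks], means, covs


def relabel_point_process(
    draws: ChainDraws, K0_hat: int, seed: int | None = 0
) -> RelabeledDraws:
    """Resolve upper-level label switching by clustering draws in the point
    process representation.

    The functional clustered across draws is the cluster moment mean, which
    is invariant under subcomponent relabeling within a cluster.  K-means is
    initialized at the functionals of the first selected draw, with seeded
    random restarts as backup.
    """
    sel = np.nonzero(draws.K0_per_draw == K0_hat)[0]
    if sel.size == 0:
        raise ValueError(
            f"no draw has exactly {K0_hat} nonempty clusters; re-run the chain "
            "or choose a different K0_hat"
        )
    per_draw = []
    points = []
    for m in sel:
        ks = np.unique(draws.S[m])
        eta, means, covs = _cluster_functionals(draws, m, ks)
        per_draw.append((m, ks, eta, means, covs))
        points.append(means)
    pooled = np.concatenate(points, axis=0)  # (M_sel * K0_hat, r)

    if K0_hat == 1:
        centers_labels = np.zeros(len(pooled), dtype=int)
    else:
        km = KMeans(
            n_clusters=K0_hat,
            init=points[0],
            n_init=1,
            random_state=None if seed is None else int(seed) % (2**31 - 1),
        ).fit(pooled)
        # one seeded multi-restart pass as backup against a poor reference draw
        km_multi = KMeans(
            n_clusters=K0_hat,
            n_init=10,
            random_state=None if seed is None else int(seed) % (2**31 - 1),
        ).fit(pooled)
        if km_multi.inertia_ < km.inertia_:
            km = km_multi
        centers_labels = km.labels_

    S_out, kept, eta_out, means_out, covs_out = [], [], [], [], []
    for j, (m, ks, eta, means, covs) in enumerate(per_draw):
        labels = centers_labels[j * K0_hat : (j + 1) * K0_hat]
        if len(np.unique(labels)) != K0_hat:
            continue  # not a permutation of the centers: drop the draw
        recode = np.empty(int(ks.max()) + 1, dtype=np.int32)
        recode[ks] = labels
        S_out.append(recode[draws.S[m]])
        order = np.argsort(labels)
        kept.append(m)
        eta_out.append(eta[order])
        means_out.append(means[order])
        covs_out.append(covs[order])
    rate = len(kept) / sel.size
    if not kept:
        raise ValueError("no draw survived the permutation check")
    return RelabeledDraws(
        S=np.stack(S_out),
        kept=np.asarray(kept),
        permutation_rate=rate,
        eta=np.stack(eta_out),
        means=np.stack(means_out),
        covs=np.stack(covs_out),
    )


def map_partition(S_relabeled: np.ndarray) -> np.ndarray:
    """Per-observation most frequent relabeled assignment (ties to smaller label)."""
    S = np.asarray(S_relabeled)
    n_labels = int(S.max()) + 1
    freq = np.stack([(S == c).sum(axis=0) for c in range(n_labels)])
    return np.argmax(freq, axis=0).astype(np.int32)


def similarity_matrix(S_draws: np.ndarray, chunk: int = 64) -> np.ndarray:
    """Co-clustering probabilities Pr{S_i = S_j | y}, label-invariant.

    Entry (i, j) is the fraction of draws assigning i and j to the same
    cluster; the diagonal is 1 by construction.
    """
    S = np.asarray(S_draws)
    M, N = S.shape
    sim = np.zeros((N, N))
    for start in range(0, M, chunk):
        block = S[start : start + chunk]
        sim += (block[:, :, None] == block[:, None, :]).sum(axis=0)
    return sim / M


def score_partition(
    est: np.ndarray, truth: np.ndarray
) -> tuple[float, float]:
    """(adjusted Rand index, misclassification rate under optimal matching).

    The misclassification rate maximizes the agreement over all one-to-one
    matchings of estimated to true labels (Hungarian algorithm on the
    contingency table), so it is invariant to label permutations.
    """
    est = np.asarray(est)
    truth = np.asarray(truth)
    if est.shape != truth.shape:
        raise ValueError("partitions must have equal length")
    ari = float(adjusted_rand_score(truth, est))
    e_labels, e_idx = np.unique(est, return_inverse=True)
    t_labels, t_idx = np.unique(truth, return_inverse=True)
    table = np.zeros((len(e_labels), len(t_labels)), dtype=np.int64)
    np.add.at(table, (e_idx, t_idx), 1)
    rows, cols = linear_sum_assignment(-table)
    agreement = table[rows, cols].sum() / len(est)
    return ari, float(1.0 - agreement)


def identify(
    draws: ChainDraws, K0_hat: int | None = None, seed: int | None = 0
) -> PartitionEstimate:
    """Full post-processing pipeline: select K0, relabel, summarize.

    The similarity matrix uses all draws (it is label-invariant); the MAP
    partition and the identified parameter summaries use only the relabeled
    draws with exactly K0_hat nonempty clusters.
    """
    if K0_hat is None:
        K0_hat = estimate_K0(draws)
    rel = relabel_point_process(draws, K0_hat, seed=seed)
    return PartitionEstimate(
        K0_hat=K0_hat,
        map_partition=map_partition(rel.S),
        similarity=similarity_matrix(draws.S),
        permutation_rate=rel.permutation_rate,
        eta=rel.eta.mean(axis=0),
        means=rel.means.mean(axis=0),
        covs=rel.covs.mean(axis=0),
    )
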
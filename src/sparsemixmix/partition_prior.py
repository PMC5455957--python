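"""Exact partition priors of the sparse finite mixture and BNP comparators.

Integrating the symmetric Dirichlet(e0) prior out of the cluster indicators
of a K-component mixture gives the exchangeable assignment prior

    p(S) = Gamma(K e0) / Gamma(N + K e0) * prod_k Gamma(N_k + e0) / Gamma(e0),

a product over all K cells (empty cells contribute 1).  Summing over the
K!/(K-K0)! assignment vectors in the equivalence class of a set partition
with K0 clusters gives a product partition model.  Its predictive rules

    p(join existing cluster k) = (N_k + e0) / (N - 1 + K e0)
    p(open a new cluster)      = (K - K0) e0 / (N - 1 + K e0)

are compared against the Chinese restaurant process (Dirichlet process,
concentration alpha) and its Pitman-Yor two-parameter generalization
(discount beta): with e0 = alpha/K the sparse mixture prior converges to the
DP prior as K grows, but for finite K the probability of opening a new
cluster *decreases* in the number of occupied clusters and the expected
number of clusters stays bounded by K as N grows, instead of growing like
alpha*log(N) (DP) or N^beta (PYP).

All probabilities are computed in log space via log-gamma.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "PartitionPriorSpec",
    "log_prior_assignment",
    "log_prior_partition",
    "predictive_existing",
    "predictive_new",
    "crp_predictive",
    "crp_log_partition",
    "expected_K0",
    "tv_distance_to_crp",
]


@dataclass(frozen=True)
class PartitionPriorSpec:
    """Sparse-mixture partition prior (K, e0) for N observations, with
    optional DP/PYP comparator parameters (alpha, beta)."""

    K: int
    e0: float
    N: int
    alpha: float | None = None
    beta: float = 0.0

    def __post_init__(self):
        if self.K < 1 or self.N < 1 or self.e0 <= 0:
            raise ValueError("need K >= 1, N >= 1, e0 > 0")
        if self.alpha is not None:
            if not (0.0 <= self.beta < 1.0):
                raise ValueError("PYP discount beta must lie in [0, 1)")
            if self.alpha <= -self.beta:
                raise ValueError("PYP requires alpha > -beta")


def _cluster_sizes(S: np.ndarray, K: int) -> np.ndarray:
    S = np.asarray(S)
    if S.min() < 0 or S.max() >= K:
        raise ValueError("labels must lie in 0..K-1")
    return np.bincount(S, minlength=K)


def log_prior_assignment(S: np.ndarray, spec: PartitionPriorSpec) -> float:
    """Log prior of one assignment vector S (labels 0..K-1) under Dirichlet(e0)."""
    sizes = _cluster_sizes(S, spec.K)
    N = len(np.asarray(S))
    e0, K = spec.e0, spec.K
    return float(
        gammaln(K * e0)
        - gammaln(N + K * e0)
        + np.sum(gammaln(sizes + e0) - gammaln(e0))
    )


def log_prior_partition(
    sizes: Sequence[int], spec: PartitionPriorSpec
) -> float:
    """Log prior of a set partition with the given cluster sizes.

    Sums the assignment prior over the K!/(K-K0)! assignment vectors in the
    partition's equivalence class; -inf if the partition has more than K
    clusters.
    """
    sizes = np.asarray(list(sizes))
    if np.any(sizes < 1):
        raise ValueError("cluster sizes must be positive")
    K0 = len(sizes)
    K, e0 = spec.K, spec.e0
    if K0 > K:
        return -np.inf
    N = int(sizes.sum())
    log_multiplicity = gammaln(K + 1) - gammaln(K - K0 + 1)
    return float(
        log_multiplicity
        + gammaln(K * e0)
        - gammaln(N + K * e0)
        + np.sum(gammaln(sizes + e0) - gammaln(e0))
    )


def predictive_existing(N_k_minus: int, spec: PartitionPriorSpec) -> float:
    """Prior predictive probability of joining an existing cluster of size N_k^{-i}."""
    return (N_k_minus + spec.e0) / (spec.N - 1 + spec.K * spec.e0)


def predictive_new(K0_minus: int, spec: PartitionPriorSpec) -> float:
    """Prior predictive probability of opening a new cluster given K0^{-i}
    nonempty clusters; decreases in K0^{-i} and vanishes at K0^{-i} = K."""
    return (spec.K - K0_minus) * spec.e0 / (spec.N - 1 + spec.K * spec.e0)


def crp_predictive(
    N_k_minus: int, K0_minus: int, spec: PartitionPriorSpec
) -> tuple[float, float]:
    """Pitman-Yor predictive rule (join cluster k, open new); beta=0 is the CRP."""
    if spec.alpha is None:
        raise ValueError("spec.alpha is required for the DP/PYP comparator")
    denom = spec.N - 1 + spec.alpha
    existing = (N_k_minus - spec.beta) / denom
    new = (spec.alpha + spec.beta * K0_minus) / denom
    return existing, new


def crp_log_partition(sizes: Sequence[int], alpha: float, beta: float = 0.0) -> float:
    """Log EPPF of the DP (beta=0) / PYP prior for a partition with given sizes."""
    sizes = np.asarray(list(sizes))
    K0 = len(sizes)
    N = int(sizes.sum())
    if beta == 0.0:
        return float(
            K0 * np.log(alpha)
            + np.sum(gammaln(sizes))
            + gammaln(alpha)
            - gammaln(alpha + N)
        )
    ratio = gammaln(alpha / beta + K0) - gammaln(alpha / beta + 1)
    return float(
        (K0 - 1) * np.log(beta)
        + ratio
        + gammaln(alpha + 1)
        - gammaln(alpha + N)
        + np.sum(gammaln(sizes - beta) - gammaln(1.0 - beta))
    )


def expected_K0(
    spec: PartitionPriorSpec,
    N_grid: Iterable[int],
    process: str = "sparse",
    max_support: int = 2000,
) -> np.ndarray:
    """Exact E[K0] along a grid of sample sizes via the sequential predictives.

    The number of occupied clusters evolves as a Markov chain whose
    transition probability of opening a new cluster at step n depends only on
    the current count: (K - K0) e0 / (n - 1 + K e0) for the sparse mixture,
    alpha / (n - 1 + alpha) for the DP, (alpha + beta K0) / (n - 1 + alpha)
    for the PYP.  The forward recursion over the K0 distribution is exact
    (the DP/PYP support is truncated at ``max_support``, with the top state
    absorbing).
    """
    N_grid = np.asarray(sorted(set(int(n) for n in N_grid)))
    if np.any(N_grid < 1):
        raise ValueError("sample sizes must be positive")
    if process == "sparse":
        cap = spec.K
    elif process in ("dp", "pyp"):
        if spec.alpha is None:
            raise ValueError("spec.alpha is required for the DP/PYP comparator")
        cap = min(int(N_grid.max()), max_support)
    else:
        raise ValueError(f"unknown process {process!r}")
    dist = np.zeros(cap + 1)
    dist[1] = 1.0
    k_states = np.arange(cap + 1, dtype=float)
    if process == "sparse":
        numer = (spec.K - k_states) * spec.e0
    elif process == "dp":
        numer = np.full(cap + 1, float(spec.alpha))
    else:
        numer = spec.alpha + spec.beta * k_states
    out = np.empty(len(N_grid))
    pos = 0
    if N_grid[0] == 1:
        out[0] = 1.0
        pos = 1
    denom_alpha = spec.K * spec.e0 if process == "sparse" else spec.alpha
    for n in range(2, int(N_grid.max()) + 1):
        p_new = numer / (n - 1 + denom_alpha)
        p_new = np.clip(p_new, 0.0, 1.0)
        p_new[-1] = 0.0  # top state absorbs (exact for sparse: K is a hard cap)
        moved = dist * p_new
        dist = dist - moved
        dist[1:] += moved[:-1]
        if pos < len(N_grid) and n == N_grid[pos]:
            out[pos] = float(dist @ k_states)
            pos += 1
    return out


def _set_partitions(n: int):
    """All set partitions of {0..n-1} as lists of blocks (restricted growth)."""
    def rec(i, blocks):
        if i == n:
            yield [list(b) for b in blocks]
            return
        for b in blocks:
            b.append(i)
            yield from rec(i + 1, blocks)
            b.pop()
        blocks.append([i])
        yield from rec(i + 1, blocks)
        blocks.pop()

    yield from rec(0, [])


def tv_distance_to_crp(N: int, K: int, e0: float, alpha: float) -> float:
    """Total variation distance between the sparse-mixture partition prior
    (K, e0) and the CRP(alpha) prior, over all set partitions of N items.

    With e0 = alpha/K this distance shrinks as K grows, tracing the
    convergence of the sparse finite mixture to the DP mixture.  Exhaustive
    enumeration; intended for desk-scale N (Bell(N) partitions).
    """
    spec = PartitionPriorSpec(K=K, e0=e0, N=N, alpha=alpha)
    tv = 0.0
    for blocks in _set_partitions(N):
        sizes = [len(b) for b in blocks]
        p_sparse = np.exp(log_prior_partition(sizes, spec))
        p_crp = np.exp(crp_log_partition(sizes, alpha))
        tv += abs(p_sparse - p_crp)
    return 0.5 * tv
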
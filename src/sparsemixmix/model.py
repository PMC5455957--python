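"""Two-level mixture density, cluster moments and the variance decomposition.

A state of the model is the full parameter set of the mixture of mixtures

    p(y) = sum_k eta_k p_k(y),      p_k(y) = sum_l w_kl N(y; mu_kl, Sigma_kl),

which is algebraically identical to an expanded single-level Gaussian mixture
with K*L components and weights eta_k * w_kl.  The cluster moments

    mu~_k = sum_l w_kl mu_kl,
    Sig~_k = sum_l w_kl (Sigma_kl + mu_kl mu_kl') - mu~_k mu~_k'

feed the three-term decomposition of the total covariance into between-cluster
spread, within-cluster subcomponent-mean spread, and average subcomponent
covariance; the trace fractions phi_B and phi_W of that decomposition are the
quantities the hierarchical prior is tuned to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "MixtureState",
    "ClusterMoments",
    "VarianceDecomposition",
    "cluster_log_density",
    "cluster_density",
    "mixture_log_density",
    "mixture_density",
    "expanded_log_density",
    "expanded_density",
    "cluster_moments",
    "variance_decomposition",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class MixtureState:
    """One complete parameter draw of the K-cluster, L-subcomponent mixture.

    Arrays: eta (K,), w (K, L), mu (K, L, r), Sigma (K, L, r, r); the
    cluster-level random hyperparameters b0 (K, r), C0 (K, r, r) and
    lam (K, r) are optional (None for purely generative states).
    """

    eta: np.ndarray
    w: np.ndarray
    mu: np.ndarray
    Sigma: np.ndarray
    b0: np.ndarray | None = None
    C0: np.ndarray | None = None
    lam: np.ndarray | None = None

    @property
    def K(self) -> int:
        return len(self.eta)

    @property
    def L(self) -> int:
        return self.w.shape[1]

    @property
    def r(self) -> int:
        return self.mu.shape[2]

    def validate(self, atol: float = 1e-8) -> "MixtureState":
        eta, w = np.asarray(self.eta), np.asarray(self.w)
        if np.any(eta < -atol) or abs(eta.sum() - 1.0) > atol:
            raise ValueError("eta must be a probability vector")
        if np.any(w < -atol) or not np.allclose(w.sum(axis=1), 1.0, atol=atol):
            raise ValueError("each w_k must be a probability vector")
        if self.mu.shape != (self.K, self.L, self.r):
            raise ValueError("mu has inconsistent shape")
        if self.Sigma.shape != (self.K, self.L, self.r, self.r):
            raise ValueError("Sigma has inconsistent shape")
        np.linalg.cholesky(self.Sigma)  # raises if any Sigma_kl is not SPD
        return self


@dataclass(frozen=True)
class ClusterMoments:
    """First and second central moments of one cluster density."""

    mean: np.ndarray
    cov: np.ndarray


@dataclass(frozen=True)
class VarianceDecomposition:
    """Cov(Y) split into its three sources, with scalar trace fractions.

    ``total = between + within_means + within_subcomp``; ``phi_B`` is the
    trace fraction of `between` in `total`, ``phi_W`` the trace fraction of
    `within_means` within the within-cluster part.  Per-dimension fractions
    (ratios of diagonals) are exposed as well because the prior tuning works
    on the diagonal of the sample covariance.
    """

    total: np.ndarray
    between: np.ndarray
    within_means: np.ndarray
    within_subcomp: np.ndarray
    phi_B: float
    phi_W: float
    phi_B_dims: np.ndarray = field(repr=False, default=None)
    phi_W_dims: np.ndarray = field(repr=False, default=None)


def _gauss_log_density(y: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """log N(y; mu_c, Sigma_c) for y (N, r) against components (C, r), (C, r, r) -> (N, C)."""
    chol = np.linalg.cholesky(Sigma)
    log_det = np.sum(np.log(np.diagonal(chol, axis1=-2, axis2=-1)), axis=-1)
    inv_chol = np.linalg.inv(chol)
    diff = y[None, :, :] - mu[:, None, :]  # (C, N, r)
    z = diff @ np.swapaxes(inv_chol, -1, -2)
    quad = np.einsum("cni,cni->cn", z, z)
    r = y.shape[1]
    return (-0.5 * r * _LOG_2PI - log_det[:, None] - 0.5 * quad).T


def _as_points(y: np.ndarray, r: int) -> tuple[np.ndarray, bool]:
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        if len(y) != r:
            raise ValueError(f"point has dimension {len(y)}, state has r={r}")
        return y[None, :], True
    return y, False


def component_log_densities(y: np.ndarray, state: MixtureState) -> np.ndarray:
    """log N(y_i; mu_kl, Sigma_kl) for all expanded components -> (N, K, L)."""
    pts, _ = _as_points(y, state.r)
    KL = state.K * state.L
    flat = _gauss_log_density(
        pts, state.mu.reshape(KL, state.r), state.Sigma.reshape(KL, state.r, state.r)
    )
    return flat.reshape(len(pts), state.K, state.L)


def cluster_log_density(y: np.ndarray, k: int, state: MixtureState) -> np.ndarray | float:
    """log p_k(y) = log sum_l w_kl N(y; mu_kl, Sigma_kl), via log-sum-exp."""
    pts, scalar = _as_points(y, state.r)
    log_comp = _gauss_log_density(pts, state.mu[k], state.Sigma[k])
    with np.errstate(divide="ignore"):
        log_w = np.log(state.w[k])
    out = logsumexp(log_comp + log_w[None, :], axis=1)
    return float(out[0]) if scalar else out


def cluster_density(y: np.ndarray, k: int, state: MixtureState) -> np.ndarray | float:
    return np.exp(cluster_log_density(y, k, state))


def mixture_log_density(y: np.ndarray, state: MixtureState) -> np.ndarray | float:
    """log p(y) of the two-level mixture, evaluated cluster by cluster."""
    pts, scalar = _as_points(y, state.r)
    log_clusters = np.stack(
        [cluster_log_density(pts, k, state) for k in range(state.K)], axis=1
    )
    with np.errstate(divide="ignore"):
        log_eta = np.log(state.eta)
    out = logsumexp(log_clusters + log_eta[None, :], axis=1)
    return float(out[0]) if scalar else out


def mixture_density(y: np.ndarray, state: MixtureState) -> np.ndarray | float:
    return np.exp(mixture_log_density(y, state))


def expanded_log_density(y: np.ndarray, state: MixtureState) -> np.ndarray | float:
    """log p(y) through the expanded K*L-component single-level mixture."""
    pts, scalar = _as_points(y, state.r)
    log_comp = component_log_densities(pts, state)
    with np.errstate(divide="ignore"):
        log_wt = np.log(state.eta[:, None]) + np.log(state.w)
    out = logsumexp(log_comp.reshape(len(pts), -1) + log_wt.reshape(-1)[None, :], axis=1)
    return float(out[0]) if scalar else out


def expanded_density(y: np.ndarray, state: MixtureState) -> np.ndarray | float:
    return np.exp(expanded_log_density(y, state))


def cluster_moments(state: MixtureState) -> list[ClusterMoments]:
    """Mean and covariance of each cluster density (moments of a Gaussian mixture)."""
    out = []
    for k in range(state.K):
        w, mu, Sig = state.w[k], state.mu[k], state.Sigma[k]
        mean = w @ mu
        second = np.einsum("l,lij->ij", w, Sig) + np.einsum("l,li,lj->ij", w, mu, mu)
        out.append(ClusterMoments(mean=mean, cov=second - np.outer(mean, mean)))
    return out


def mixture_mean(state: MixtureState) -> np.ndarray:
    return state.eta @ np.array([m.mean for m in cluster_moments(state)])


def variance_decomposition(state: MixtureState) -> VarianceDecomposition:
    """Three-term split of Cov(Y) and the implied phi_B / phi_W fractions.

    between       = sum_k eta_k (mu~_k - E Y)(mu~_k - E Y)'
    within_means  = sum_k eta_k sum_l w_kl (mu_kl - mu~_k)(mu_kl - mu~_k)'
    within_subcomp= sum_k eta_k sum_l w_kl Sigma_kl
    """
    moments = cluster_moments(state)
    means = np.array([m.mean for m in moments])  # (K, r)
    grand = state.eta @ means
    dev = means - grand
    between = np.einsum("k,ki,kj->ij", state.eta, dev, dev)
    mu_dev = state.mu - means[:, None, :]
    within_means = np.einsum("k,kl,kli,klj->ij", state.eta, state.w, mu_dev, mu_dev)
    within_subcomp = np.einsum("k,kl,klij->ij", state.eta, state.w, state.Sigma)
    total = between + within_means + within_subcomp
    within = within_means + within_subcomp
    tr = np.trace
    phi_B = float(tr(between) / tr(total))
    tr_within = tr(within)
    phi_W = float(tr(within_means) / tr_within) if tr_within > 0 else 0.0
    d_tot = np.diag(total)
    d_within = np.diag(within)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_B_dims = np.where(d_tot > 0, np.diag(between) / d_tot, 0.0)
        phi_W_dims = np.where(d_within > 0, np.diag(within_means) / d_within, 0.0)
    return VarianceDecomposition(
        total=total,
        between=between,
        within_means=within_means,
        within_subcomp=within_subcomp,
        phi_B=phi_B,
        phi_W=phi_W,
        phi_B_dims=phi_B_dims,
        phi_W_dims=phi_W_dims,
    )
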
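"""Seeded generators for the simulation regimes the method is designed for.

Three data shapes are provided:

* ``gaussian`` — a unit-covariance Gaussian mixture whose component means are
  placed and scaled analytically so that the between-cluster trace fraction
  of the variance decomposition equals ``phi_B_target`` exactly;
* ``mixmix`` — non-Gaussian clusters, each a mixture of overlapping Gaussian
  subcomponents whose mean spread is solved so the within-cluster fraction
  equals ``phi_W_target`` exactly (the generating state round-trips through
  :func:`sparsemixmix.model.variance_decomposition` to machine precision);
* ``sal_like`` — comet-shaped clusters with one heavy exponential tail along
  a random axis, qualitatively like shifted asymmetric Laplace draws; a
  stress regime the default prior is *not* tuned for.

The phi targets are enforced on the generating parameters, not on the finite
sample, so acceptance-style round-trip checks compare implied (analytic)
fractions.  Cluster centers sit at the vertices of a regular simplex (or a
regular polygon in two dimensions when there are more clusters than r+1),
which is symmetric and analytically scalable in any dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MixtureState

__all__ = [
    "SyntheticSpec",
    "gen_gaussian_phiB",
    "gen_mixmix",
    "gen_sal_like",
    "generate",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of one synthetic dataset.

    ``phi_B_target`` defaults to 0.9: clusters that are well separated
    relative to their spread, the regime the clustering method targets
    (clusters are dense regions with clear gaps between them).
    ``phi_W_target`` defaults to 0.1, matching the prior's default notion of
    strongly overlapping subcomponents.
    """

    n_obs: int
    n_dims: int = 2
    n_clusters: int = 4
    subcomps_per_cluster: int = 2
    phi_B_target: float = 0.9
    phi_W_target: float = 0.1
    weights: np.ndarray | None = None
    shape: str = "mixmix"
    seed: int | None = None
    sal_rate: float = 1.0

    def cluster_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.full(self.n_clusters, 1.0 / self.n_clusters)
        w = np.asarray(self.weights, dtype=float)
        if len(w) != self.n_clusters or abs(w.sum() - 1.0) > 1e-8 or np.any(w <= 0):
            raise ValueError("weights must be positive and sum to 1 over n_clusters")
        return w

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _check_phi(name: str, value: float) -> None:
    if not (0.0 < value < 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1), got {value}")


def _simplex_vertices(n_points: int, r: int) -> np.ndarray:
    """Vertices of a regular (n_points-1)-simplex embedded in r dims (needs n_points <= r+1)."""
    basis = np.eye(n_points)
    centered = basis - basis.mean(axis=0)
    # the centered vertices span an (n_points-1)-dim subspace; rotate into it
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    coords = centered @ vt.T[:, : n_points - 1] if n_points > 1 else np.zeros((1, 0))
    out = np.zeros((n_points, r))
    out[:, : coords.shape[1]] = coords
    return out


def _spread_points(n_points: int, r: int, rng: np.random.Generator) -> np.ndarray:
    """A nondegenerate, well-spread configuration of n_points in r dims."""
    if n_points == 1:
        return np.zeros((1, r))
    if n_points <= r + 1:
        return _simplex_vertices(n_points, r)
    if r == 2:
        angles = 2.0 * np.pi * np.arange(n_points) / n_points
        return np.stack([np.cos(angles), np.sin(angles)], axis=1)
    if r == 1:
        return np.linspace(-1.0, 1.0, n_points)[:, None]
    pts = rng.standard_normal((n_points, r))
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _scaled_centered(
    points: np.ndarray, weights: np.ndarray, target_trace: float
) -> np.ndarray:
    """Center `points` under `weights` and scale so tr(sum_k w_k c_k c_k') = target."""
    centered = points - weights @ points
    t0 = float(np.einsum("k,ki,ki->", weights, centered, centered))
    if target_trace == 0.0:
        return np.zeros_like(centered)
    if t0 <= 0.0:
        raise ValueError("degenerate center configuration")
    return centered * np.sqrt(target_trace / t0)


def _sample_labels(
    weights: np.ndarray, n_obs: int, rng: np.random.Generator
) -> np.ndarray:
    return rng.choice(len(weights), size=n_obs, p=weights)


def gen_gaussian_phiB(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, MixtureState]:
    """Unit-covariance Gaussian mixture hitting phi_B_target exactly.

    Returns (data, labels, generating_state); the generating state has one
    subcomponent per cluster, so its variance decomposition has
    phi_B = phi_B_target and phi_W = 0 analytically.
    """
    _check_phi("phi_B_target", spec.phi_B_target)
    rng = spec.rng() if rng is None else rng
    K, r = spec.n_clusters, spec.n_dims
    eta = spec.cluster_weights()
    # unit covariances contribute trace r; solve the between trace from phi_B
    between_trace = (
        0.0 if K == 1 else spec.phi_B_target / (1.0 - spec.phi_B_target) * r
    )
    centers = _scaled_centered(_spread_points(K, r, rng), eta, between_trace)
    state = MixtureState(
        eta=eta,
        w=np.ones((K, 1)),
        mu=centers[:, None, :],
        Sigma=np.broadcast_to(np.eye(r), (K, 1, r, r)).copy(),
    )
    labels = _sample_labels(eta, spec.n_obs, rng)
    data = centers[labels] + rng.standard_normal((spec.n_obs, r))
    return data, labels, state


def gen_mixmix(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, MixtureState]:
    """Non-Gaussian clusters built from overlapping Gaussian subcomponents.

    The total trace is normalized to r; between-cluster, subcomponent-mean
    and subcomponent-covariance traces are then phi_B*r,
    phi_W*(1-phi_B)*r and (1-phi_B)*(1-phi_W)*r, solved exactly on the
    generating parameters.  Raises if the implied subcomponent-mean spacing
    would exceed twice the average subcomponent standard deviation, i.e. if
    the cluster densities would no longer be dense and connected.
    """
    _check_phi("phi_B_target", spec.phi_B_target)
    _check_phi("phi_W_target", spec.phi_W_target)
    rng = spec.rng() if rng is None else rng
    K, r, L = spec.n_clusters, spec.n_dims, spec.subcomps_per_cluster
    if L == 1:
        return gen_gaussian_phiB(spec, rng)
    eta = spec.cluster_weights()
    w_sub = np.full(L, 1.0 / L)
    phi_B, phi_W = spec.phi_B_target, spec.phi_W_target
    between_trace = 0.0 if K == 1 else phi_B * r
    within_mean_trace = phi_W * (1.0 - phi_B) * r
    sigma2 = (1.0 - phi_B) * (1.0 - phi_W)

    centers = _scaled_centered(_spread_points(K, r, rng), eta, between_trace)
    mu = np.empty((K, L, r))
    for k in range(K):
        # each cluster carries the same within-mean trace; eta-weighting then
        # reproduces the target exactly for any cluster weights
        dev = _scaled_centered(_spread_points(L, r, rng), w_sub, within_mean_trace)
        mu[k] = centers[k] + dev
        dists = np.linalg.norm(dev[:, None, :] - dev[None, :, :], axis=2)
        nearest = dists[~np.eye(L, dtype=bool)].reshape(L, L - 1).min()
        if nearest > 2.0 * np.sqrt(sigma2):
            raise ValueError(
                "infeasible targets: subcomponent means are separated by more "
                "than twice the subcomponent standard deviation; lower "
                "phi_W_target to keep clusters dense and connected"
            )
    Sigma = np.broadcast_to(sigma2 * np.eye(r), (K, L, r, r)).copy()
    state = MixtureState(eta=eta, w=np.tile(w_sub, (K, 1)), mu=mu, Sigma=Sigma)
    labels = _sample_labels(eta, spec.n_obs, rng)
    sub = rng.choice(L, size=spec.n_obs, p=w_sub)
    data = mu[labels, sub] + np.sqrt(sigma2) * rng.standard_normal((spec.n_obs, r))
    return data, labels, state


def gen_sal_like(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Comet-shaped, heavy-tailed asymmetric clusters.

    Each cluster is a location shift plus an exponential radial factor (rate
    ``sal_rate``) along a cluster-specific random axis plus isotropic Gaussian
    noise; along the axis the cluster is strongly right-skewed (skewness > 1
    for the default rate).  Returned as (data, labels) only — the generating
    density is not in the Gaussian mixture family.
    """
    _check_phi("phi_B_target", spec.phi_B_target)
    rng = spec.rng() if rng is None else rng
    K, r = spec.n_clusters, spec.n_dims
    eta = spec.cluster_weights()
    rate = spec.sal_rate
    noise_sd = 0.3  # fixed: as rate grows the tail vanishes and clusters turn Gaussian
    # within-cluster trace: exponential variance along the axis + noise
    within_trace = 1.0 / rate**2 + r * noise_sd**2
    between_trace = (
        0.0 if K == 1 else spec.phi_B_target / (1.0 - spec.phi_B_target) * within_trace
    )
    centers = _scaled_centered(_spread_points(K, r, rng), eta, between_trace)
    axes = rng.standard_normal((K, r))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    labels = _sample_labels(eta, spec.n_obs, rng)
    radial = rng.exponential(scale=1.0 / rate, size=spec.n_obs)
    data = (
        centers[labels]
        + radial[:, None] * axes[labels]
        + noise_sd * rng.standard_normal((spec.n_obs, r))
    )
    return data, labels


def generate(spec: SyntheticSpec):
    """Dispatch on ``spec.shape`` (gaussian | mixmix | sal_like)."""
    if spec.shape == "gaussian":
        return gen_gaussian_phiB(spec)
    if spec.shape == "mixmix":
        return gen_mixmix(spec)
    if spec.shape == "sal_like":
        return gen_sal_like(spec)
    raise ValueError(f"unknown shape {spec.shape!r}")
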
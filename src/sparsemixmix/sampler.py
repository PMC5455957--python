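"""Data-augmented Gibbs sampler for the sparse hierarchical mixture of mixtures.

The augmented state is (S, I, eta, w, mu, Sigma, b0, C0, lambda): per
observation a cluster indicator S_i in {1..K} and a subcomponent indicator
I_i in {1..L}, plus all parameters of the hierarchy.  Every full conditional
is standard:

1. (S_i, I_i) jointly from the K*L-cell categorical with probabilities
   proportional to eta_k w_kl N(y_i; mu_kl, Sigma_kl) (log-space);
2. eta ~ Dirichlet(e0 + N_k), w_k ~ Dirichlet(d0 + N_kl);
3. mu_kl from the conjugate normal combining the N(b0k, Lam^1/2 B0 Lam^1/2)
   prior with the N_kl assigned observations;
4. Sigma_kl ~ IW(c0 + N_kl/2, C0k + scatter/2);
5. b0k from the conjugate normal with the L subcomponent means as
   pseudo-observations;
6. C0k ~ W(g0 + L*c0, G0 + sum_l Sigma_kl^{-1});
7. lambda_kj from its generalized inverse Gaussian full conditional
   GIG(p = nu - L/2, a = 2*nu, b = sum_l (mu_klj - b0kj)^2 / B0_jj).

Empty clusters and subcomponents are refreshed from the prior each sweep;
with e0 = 0.001 superfluous clusters empty out and stay empty, so the number
of nonempty clusters per draw, K0, estimates the number of data clusters.
No identifiability constraint is imposed during sampling — label switching is
resolved afterwards (:mod:`sparsemixmix.postprocess`).

Matrix conventions are those of :mod:`sparsemixmix._wishart`.  A single
seeded :class:`numpy.random.Generator` is threaded through every step in the
fixed sweep order above, so runs are bit-reproducible given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._gig import sample_gig
from ._wishart import sample_invwishart, sample_wishart
from .hyperprior import HyperParams
from .model import MixtureState, component_log_densities, expanded_log_density

logger = logging.getLogger(__name__)

__all__ = [
    "AllocationPair",
    "ChainDraws",
    "update_allocations",
    "update_weights",
    "update_subcomponent_means",
    "update_subcomponent_covs",
    "update_cluster_centers",
    "update_cluster_scales",
    "update_local_shrinkage",
    "gibbs_sweep",
    "run_chain",
    "validation_hyperparams",
    "successive_conditional_draws",
    "geweke_z_scores",
]

_GIG_GAMMA_LIMIT = 1e-300  # below this the quadratic term is treated as zero


@dataclass(frozen=True)
class AllocationPair:
    """Cluster and subcomponent indicators (0-based) with their counts."""

    S: np.ndarray
    I: np.ndarray
    N_k: np.ndarray
    N_kl: np.ndarray


@dataclass
class ChainDraws:
    """Post-burn-in draws, iteration-major, plus run metadata."""

    eta: np.ndarray  # (M, K)
    w: np.ndarray  # (M, K, L)
    mu: np.ndarray  # (M, K, L, r)
    Sigma: np.ndarray  # (M, K, L, r, r)
    b0: np.ndarray  # (M, K, r)
    C0: np.ndarray  # (M, K, r, r)
    lam: np.ndarray  # (M, K, r)
    S: np.ndarray  # (M, N) int32
    I: np.ndarray  # (M, N) int32
    K0_per_draw: np.ndarray  # (M,)
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.eta.shape[0]

    def state(self, m: int) -> MixtureState:
        return MixtureState(
            eta=self.eta[m],
            w=self.w[m],
            mu=self.mu[m],
            Sigma=self.Sigma[m],
            b0=self.b0[m],
            C0=self.C0[m],
            lam=self.lam[m],
        )


def _dirichlet(alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet draw along the last axis, robust to underflow at tiny alpha.

    With alpha as small as e0 = 0.001 the gamma draws can all underflow to
    zero; the limiting distribution is then a uniformly random vertex.
    """
    g = rng.gamma(shape=alpha)
    total = g.sum(axis=-1, keepdims=True)
    bad = np.nonzero(total.reshape(-1) == 0.0)[0]
    if bad.size:
        flat = g.reshape(-1, g.shape[-1])
        for row in bad:
            flat[row, rng.integers(flat.shape[-1])] = 1.0
        total = g.sum(axis=-1, keepdims=True)
    return g / total


def update_allocations(
    y: np.ndarray, state: MixtureState, rng: np.random.Generator
) -> AllocationPair:
    """Joint draw of (S_i, I_i) from the expanded-mixture responsibilities."""
    N = len(y)
    K, L = state.K, state.L
    log_comp = component_log_densities(y, state)  # (N, K, L)
    with np.errstate(divide="ignore"):
        log_wt = np.log(state.eta)[:, None] + np.log(state.w)
    logp = (log_comp + log_wt[None, :, :]).reshape(N, K * L)
    finite = np.isfinite(logp.max(axis=1))
    if not finite.all():
        raise FloatingPointError(
            f"all component log-probabilities underflowed for observation "
            f"{int(np.nonzero(~finite)[0][0])}"
        )
    # Gumbel-max trick: one categorical draw per row in log space
    idx = np.argmax(logp + rng.gumbel(size=logp.shape), axis=1)
    S = (idx // L).astype(np.int32)
    I = (idx % L).astype(np.int32)
    N_kl = np.bincount(idx, minlength=K * L).reshape(K, L)
    return AllocationPair(S=S, I=I, N_k=N_kl.sum(axis=1), N_kl=N_kl)


def update_weights(
    alloc: AllocationPair, h: HyperParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Conjugate Dirichlet updates of the cluster and subcomponent weights."""
    eta = _dirichlet(h.e0 + alloc.N_k.astype(float), rng)
    w = _dirichlet(h.d0 + alloc.N_kl.astype(float), rng)
    return eta, w


def _lambda_cov(h: HyperParams, lam_k: np.ndarray) -> np.ndarray:
    """Lam^1/2 B0 Lam^1/2 for one cluster."""
    s = np.sqrt(lam_k)
    return s[:, None] * h.B0 * s[None, :]


def _component_sums(
    y: np.ndarray, alloc: AllocationPair, K: int, L: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-component sums of y and of y y' (flat component index k*L+l)."""
    r = y.shape[1]
    comp = alloc.S.astype(np.int64) * L + alloc.I
    sums = np.stack(
        [np.bincount(comp, weights=y[:, i], minlength=K * L) for i in range(r)], axis=1
    )
    scatters = np.empty((K * L, r, r))
    for i in range(r):
        for j in range(i + 1):
            acc = np.bincount(comp, weights=y[:, i] * y[:, j], minlength=K * L)
            scatters[:, i, j] = acc
            scatters[:, j, i] = acc
    return sums.reshape(K, L, r), scatters.reshape(K, L, r, r)


def update_subcomponent_means(
    y: np.ndarray,
    alloc: AllocationPair,
    state: MixtureState,
    h: HyperParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conjugate normal update of every mu_kl; empty subcomponents get prior draws."""
    K, L, r = state.K, state.L, state.r
    sums, _ = _component_sums(y, alloc, K, L)
    mu = np.empty((K, L, r))
    for k in range(K):
        B_lam = _lambda_cov(h, state.lam[k])
        prior_prec = np.linalg.inv(B_lam)
        prior_term = prior_prec @ state.b0[k]
        for l in range(L):
            n = alloc.N_kl[k, l]
            if n == 0:
                mu[k, l] = rng.multivariate_normal(state.b0[k], B_lam, method="cholesky")
                continue
            lik_prec = n * np.linalg.inv(state.Sigma[k, l])
            post_prec = prior_prec + lik_prec
            cov = np.linalg.inv(post_prec)
            cov = 0.5 * (cov + cov.T)
            mean = cov @ (prior_term + np.linalg.solve(state.Sigma[k, l], sums[k, l]))
            mu[k, l] = rng.multivariate_normal(mean, cov, method="cholesky")
    return mu


def update_subcomponent_covs(
    y: np.ndarray,
    alloc: AllocationPair,
    state: MixtureState,
    h: HyperParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conjugate IW(c0 + N_kl/2, C0k + scatter/2) update of every Sigma_kl."""
    K, L, r = state.K, state.L, state.r
    sums, scatters = _component_sums(y, alloc, K, L)
    n = alloc.N_kl.astype(float)  # (K, L)
    mu = state.mu
    # centered scatter: sum (y - mu)(y - mu)' assembled from raw moments
    centered = (
        scatters
        - np.einsum("kli,klj->klij", sums, mu)
        - np.einsum("kli,klj->klij", mu, sums)
        + n[:, :, None, None] * np.einsum("kli,klj->klij", mu, mu)
    )
    c_post = h.c0 + 0.5 * n.reshape(-1)
    C_post = state.C0[:, None, :, :] + 0.5 * centered
    C_post = C_post.reshape(K * L, r, r)
    C_post = 0.5 * (C_post + np.swapaxes(C_post, -1, -2))
    Sigma = sample_invwishart(c_post, C_post, K * L, rng)
    return Sigma.reshape(K, L, r, r)


def update_cluster_centers(
    state: MixtureState, h: HyperParams, rng: np.random.Generator
) -> np.ndarray:
    """Update b0k treating the L subcomponent means as pseudo-observations."""
    K, L, r = state.K, state.L, state.r
    M0_inv = np.linalg.inv(h.M0)
    prior_term = M0_inv @ h.m0
    b0 = np.empty((K, r))
    for k in range(K):
        B_lam_inv = np.linalg.inv(_lambda_cov(h, state.lam[k]))
        post_prec = M0_inv + L * B_lam_inv
        cov = np.linalg.inv(post_prec)
        cov = 0.5 * (cov + cov.T)
        mean = cov @ (prior_term + B_lam_inv @ state.mu[k].sum(axis=0))
        b0[k] = rng.multivariate_normal(mean, cov, method="cholesky")
    return b0


def update_cluster_scales(
    state: MixtureState, h: HyperParams, rng: np.random.Generator
) -> np.ndarray:
    """Wishart update C0k ~ W(g0 + L c0, G0 + sum_l Sigma_kl^{-1})."""
    K, L, r = state.K, state.L, state.r
    if h.fix_C0:
        return np.broadcast_to(h.C0_fixed, (K, r, r)).copy()
    prec_sum = np.linalg.inv(state.Sigma).sum(axis=1)  # (K, r, r)
    rate = h.G0[None, :, :] + prec_sum
    rate = 0.5 * (rate + np.swapaxes(rate, -1, -2))
    return sample_wishart(h.g0 + L * h.c0, rate, K, rng)


def _sample_gig(
    p: float, a: float, b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """GIG(p, a, b) draws, density ~ x^(p-1) exp(-(a x + b/x)/2), elementwise in b.

    When the quadratic term b underflows and p > 0 the distribution collapses
    to its Gamma(p, a/2) limit, which is used as a fallback.
    """
    b = np.asarray(b, dtype=float)
    out = np.empty_like(b)
    tiny = b < _GIG_GAMMA_LIMIT
    if tiny.any():
        if p <= 0:
            b = np.where(tiny, _GIG_GAMMA_LIMIT, b)
            tiny = np.zeros_like(tiny)
        else:
            out[tiny] = rng.gamma(shape=p, scale=2.0 / a, size=int(tiny.sum()))
    if (~tiny).any():
        out[~tiny] = sample_gig(p, a, b[~tiny], rng)
    return out


def update_local_shrinkage(
    state: MixtureState, h: HyperParams, rng: np.random.Generator
) -> np.ndarray:
    """GIG update of the per-dimension shrinkage factors lambda_kj."""
    K, L, r = state.K, state.L, state.r
    if h.fix_lambda:
        return np.ones((K, r))
    B0_diag = np.diag(h.B0)
    if not np.allclose(h.B0, np.diag(B0_diag)):
        raise ValueError("local shrinkage update requires a diagonal B0")
    dev = state.mu - state.b0[:, None, :]  # (K, L, r)
    b = (dev**2).sum(axis=1) / B0_diag[None, :]  # (K, r)
    lam = _sample_gig(h.nu - L / 2.0, 2.0 * h.nu, b.reshape(-1), rng)
    return lam.reshape(K, r)


def _prior_cluster_hypers(
    h: HyperParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched prior draw of (b0, C0, lambda) for all K clusters."""
    K, r = h.K, h.r
    b0 = rng.multivariate_normal(h.m0, h.M0, size=K, method="cholesky")
    if h.fix_C0:
        C0 = np.broadcast_to(h.C0_fixed, (K, r, r)).copy()
    else:
        C0 = sample_wishart(h.g0, h.G0, K, rng)
    if h.fix_lambda:
        lam = np.ones((K, r))
    else:
        lam = rng.gamma(shape=h.nu, scale=1.0 / h.nu, size=(K, r))
    return b0, C0, lam


def prior_state(h: HyperParams, rng: np.random.Generator) -> MixtureState:
    """One complete draw of all parameters from the hierarchical prior."""
    K, L, r = h.K, h.L, h.r
    b0, C0, lam = _prior_cluster_hypers(h, rng)
    eta = _dirichlet(np.full(K, h.e0), rng)
    w = _dirichlet(np.full((K, L), h.d0), rng)
    mu = np.empty((K, L, r))
    Sigma = np.empty((K, L, r, r))
    for k in range(K):
        B_lam = _lambda_cov(h, lam[k])
        mu[k] = rng.multivariate_normal(b0[k], B_lam, size=L, method="cholesky")
        Sigma[k] = sample_invwishart(h.c0, C0[k], L, rng)
    return MixtureState(eta=eta, w=w, mu=mu, Sigma=Sigma, b0=b0, C0=C0, lam=lam)


def _parameter_sweep(
    y: np.ndarray,
    alloc: AllocationPair,
    state: MixtureState,
    h: HyperParams,
    rng: np.random.Generator,
) -> MixtureState:
    """All parameter-block updates given fixed allocations (sweep order fixed)."""
    eta, w = update_weights(alloc, h, rng)
    state = MixtureState(
        eta=eta, w=w, mu=state.mu, Sigma=state.Sigma, b0=state.b0, C0=state.C0, lam=state.lam
    )
    mu = update_subcomponent_means(y, alloc, state, h, rng)
    state = MixtureState(eta=eta, w=w, mu=mu, Sigma=state.Sigma, b0=state.b0, C0=state.C0, lam=state.lam)
    Sigma = update_subcomponent_covs(y, alloc, state, h, rng)
    state = MixtureState(eta=eta, w=w, mu=mu, Sigma=Sigma, b0=state.b0, C0=state.C0, lam=state.lam)
    b0 = update_cluster_centers(state, h, rng)
    state = MixtureState(eta=eta, w=w, mu=mu, Sigma=Sigma, b0=b0, C0=state.C0, lam=state.lam)
    C0 = update_cluster_scales(state, h, rng)
    state = MixtureState(eta=eta, w=w, mu=mu, Sigma=Sigma, b0=b0, C0=C0, lam=state.lam)
    lam = update_local_shrinkage(state, h, rng)
    return MixtureState(eta=eta, w=w, mu=mu, Sigma=Sigma, b0=b0, C0=C0, lam=lam)


def gibbs_sweep(
    y: np.ndarray, state: MixtureState, h: HyperParams, rng: np.random.Generator
) -> tuple[MixtureState, AllocationPair]:
    """One full sweep: allocations, weights, subcomponent parameters,
    cluster-level hyperparameters, shrinkage factors."""
    alloc = update_allocations(y, state, rng)
    return _parameter_sweep(y, alloc, state, h, rng), alloc


def _init_allocations(
    y: np.ndarray, h: HyperParams, rng: np.random.Generator, init: str
) -> AllocationPair:
    N = len(y)
    K, L = h.K, h.L
    if init == "kmeans" and N >= K:
        from sklearn.cluster import KMeans

        km = KMeans(
            n_clusters=K, n_init=5, random_state=int(rng.integers(2**31 - 1))
        ).fit(y)
        S = km.labels_.astype(np.int32)
    elif init in ("kmeans", "random"):
        S = rng.integers(K, size=N).astype(np.int32)
    else:
        raise ValueError(f"unknown init {init!r}; use 'kmeans' or 'random'")
    I = rng.integers(L, size=N).astype(np.int32)
    N_kl = np.bincount(S.astype(np.int64) * L + I, minlength=K * L).reshape(K, L)
    return AllocationPair(S=S, I=I, N_k=N_kl.sum(axis=1), N_kl=N_kl)


def run_chain(
    y: np.ndarray,
    h: HyperParams,
    n_iter: int = 4000,
    burnin: int = 4000,
    seed: int | None = None,
    init: str = "kmeans",
    log_every: int = 100,
) -> ChainDraws:
    """Run the Gibbs sampler and store the post-burn-in draws.

    Initialization partitions the data into K groups by k-means (``init="kmeans"``,
    the default; ``"random"`` assigns uniformly), draws the cluster-level
    hyperparameters from the prior, and performs one parameter sweep
    conditional on the initial allocations.  The defaults of 4000 retained
    iterations after a burn-in of 4000 follow the reference analyses.
    Deterministic given ``seed``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if not np.all(np.isfinite(y)):
        raise ValueError("data contain non-finite entries")
    if n_iter < 1 or burnin < 1:
        raise ValueError("n_iter and burnin must be at least 1")
    h.validate()
    K, L, r = h.K, h.L, h.r
    N = len(y)
    rng = np.random.default_rng(seed)
    alloc = _init_allocations(y, h, rng, init)
    state = prior_state(h, rng)
    state = _parameter_sweep(y, alloc, state, h, rng)

    M = n_iter
    draws = ChainDraws(
        eta=np.empty((M, K)),
        w=np.empty((M, K, L)),
        mu=np.empty((M, K, L, r)),
        Sigma=np.empty((M, K, L, r, r)),
        b0=np.empty((M, K, r)),
        C0=np.empty((M, K, r, r)),
        lam=np.empty((M, K, r)),
        S=np.empty((M, N), dtype=np.int32),
        I=np.empty((M, N), dtype=np.int32),
        K0_per_draw=np.empty(M, dtype=np.int64),
        meta={
            "n_iter": n_iter,
            "burnin": burnin,
            "seed": seed,
            "init": init,
            "n_obs": N,
            "hyperparams": _hyper_to_dict(h),
        },
    )
    total = burnin + n_iter
    for it in range(total):
        try:
            state, alloc = gibbs_sweep(y, state, h, rng)
        except Exception as err:
            raise RuntimeError(f"Gibbs sweep failed at iteration {it}") from err
        K0 = int((alloc.N_k > 0).sum())
        if log_every and (it + 1) % log_every == 0 and logger.isEnabledFor(logging.INFO):
            ll = float(np.sum(expanded_log_density(y, state)))
            logger.info("iter %d/%d K0=%d loglik=%.2f", it + 1, total, K0, ll)
        if it >= burnin:
            m = it - burnin
            draws.eta[m] = state.eta
            draws.w[m] = state.w
            draws.mu[m] = state.mu
            draws.Sigma[m] = state.Sigma
            draws.b0[m] = state.b0
            draws.C0[m] = state.C0
            draws.lam[m] = state.lam
            draws.S[m] = alloc.S
            draws.I[m] = alloc.I
            draws.K0_per_draw[m] = K0
    return draws


def _hyper_to_dict(h: HyperParams) -> dict[str, Any]:
    out = {}
    for name in HyperParams.__dataclass_fields__:
        val = getattr(h, name)
        out[name] = val.tolist() if isinstance(val, np.ndarray) else val
    return out


# ---------------------------------------------------------------------------
# sampler validation: successive-conditional (getting-it-right) simulation
# ---------------------------------------------------------------------------


def validation_hyperparams(r: int = 2, K: int = 3, L: int = 2) -> HyperParams:
    """A small hyperparameter set for successive-conditional sampler checks.

    All scale matrices are of the same order (M0 = I, B0 = I/2, prior mean of
    Sigma_kl = I) and e0 is moderate, so the validation chain mixes within a
    few sweeps and batch-means standard errors are trustworthy at ~10^4
    sweeps.  The data-analysis defaults (tiny e0, M0 = 10 S_y >> B0) satisfy
    the same full conditionals but would need far longer validation chains.
    """
    from .hyperprior import subcomponent_dim

    c0, g0 = 2.5 + (r - 1) / 2, 0.5 + (r - 1) / 2
    return HyperParams(
        K=K,
        L=L,
        e0=0.5,
        d0=subcomponent_dim(r) / 2 + 2,
        c0=c0,
        g0=g0,
        G0=np.eye(r) * g0 / (c0 - (r + 1) / 2),  # prior mean of Sigma_kl = I
        B0=0.5 * np.eye(r),
        m0=np.zeros(r),
        M0=np.eye(r),
        nu=10.0,
    ).validate()


def successive_conditional_draws(
    h: HyperParams, n_obs: int, n_sweeps: int, seed: int | None = None
) -> dict[str, np.ndarray]:
    """Alternate data simulation and Gibbs sweeps; parameters stay prior-distributed.

    Starting from a joint prior draw of (parameters, allocations), each sweep
    first re-simulates the data given the current allocations and parameters
    and then applies one full Gibbs sweep to the simulated data.  The
    stationary marginal of the parameters is the prior, so comparing chain
    moments of eta, lambda and b0 against their analytic prior moments
    exercises every full conditional jointly.
    """
    rng = np.random.default_rng(seed)
    K, L, r = h.K, h.L, h.r
    state = prior_state(h, rng)
    # allocations from their prior given the weights
    S = np.searchsorted(np.cumsum(state.eta), rng.random(n_obs)).astype(np.int32)
    S = np.minimum(S, K - 1)
    I = np.empty(n_obs, dtype=np.int32)
    for k in range(K):
        mask = S == k
        if mask.any():
            I[mask] = np.searchsorted(
                np.cumsum(state.w[k]), rng.random(int(mask.sum()))
            ).astype(np.int32)
    I = np.minimum(I, L - 1)
    eta_draws = np.empty((n_sweeps, K))
    lam_draws = np.empty((n_sweeps, K, r))
    b0_draws = np.empty((n_sweeps, K, r))
    chol = np.linalg.cholesky(state.Sigma)
    for m in range(n_sweeps):
        # y ~ p(y | S, I, parameters)
        z = rng.standard_normal((n_obs, r))
        y = state.mu[S, I] + np.einsum("nij,nj->ni", chol[S, I], z)
        state, alloc = gibbs_sweep(y, state, h, rng)
        S, I = alloc.S, alloc.I
        chol = np.linalg.cholesky(state.Sigma)
        eta_draws[m] = state.eta
        lam_draws[m] = state.lam
        b0_draws[m] = state.b0
    return {"eta": eta_draws, "lam": lam_draws, "b0": b0_draws}


def _batch_mean_z(x: np.ndarray, target: float, n_batches: int = 25) -> float:
    """z-score of the chain mean against `target`, batch-means standard error."""
    n = len(x) - len(x) % n_batches
    batches = x[:n].reshape(n_batches, -1).mean(axis=1)
    se = batches.std(ddof=1) / np.sqrt(n_batches)
    if se == 0.0:
        return 0.0 if np.isclose(batches.mean(), target) else np.inf
    return float((x[:n].mean() - target) / se)


def geweke_z_scores(
    h: HyperParams, n_obs: int = 10, n_sweeps: int = 10_000, seed: int | None = None
) -> dict[str, np.ndarray]:
    """Getting-it-right z-scores for first and second moments of eta, lambda, b0.

    Returns arrays of z-scores (batch-means standard errors) comparing the
    successive-conditional chain to the analytic prior moments:
    E[eta_k] = 1/K and E[eta_k^2] = (e0+1)/(K(K e0 + 1)); E[lambda] = 1 and
    E[lambda^2] = 1 + 1/nu; E[b0_j] = m0_j and E[b0_j^2] = m0_j^2 + M0_jj.
    |z| below ~4 for all entries is consistent with a correct sampler.
    """
    draws = successive_conditional_draws(h, n_obs, n_sweeps, seed)
    K, r = h.K, h.r
    zs: dict[str, np.ndarray] = {}
    e_eta = 1.0 / K
    e_eta2 = (h.e0 + 1.0) / (K * (K * h.e0 + 1.0))
    zs["eta_mean"] = np.array(
        [_batch_mean_z(draws["eta"][:, k], e_eta) for k in range(K)]
    )
    zs["eta_second"] = np.array(
        [_batch_mean_z(draws["eta"][:, k] ** 2, e_eta2) for k in range(K)]
    )
    if not h.fix_lambda:
        lam = draws["lam"].reshape(len(draws["lam"]), -1)
        zs["lam_mean"] = np.array(
            [_batch_mean_z(lam[:, j], 1.0) for j in range(lam.shape[1])]
        )
        zs["lam_second"] = np.array(
            [_batch_mean_z(lam[:, j] ** 2, 1.0 + 1.0 / h.nu) for j in range(lam.shape[1])]
        )
    m0 = np.asarray(h.m0)
    M0d = np.diag(np.asarray(h.M0))
    b0 = draws["b0"]
    zs["b0_mean"] = np.array(
        [_batch_mean_z(b0[:, k, j], m0[j]) for k in range(K) for j in range(r)]
    )
    zs["b0_second"] = np.array(
        [
            _batch_mean_z(b0[:, k, j] ** 2, m0[j] ** 2 + M0d[j])
            for k in range(K)
            for j in range(r)
        ]
    )
    return zs
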
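"""Full conditionals of the Gibbs sampler against closed-form and quadrature oracles."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from sparsemixmix.hyperprior import HyperParams, tune_hyperparams
from sparsemixmix.model import MixtureState
from sparsemixmix.sampler import (
    AllocationPair,
    update_allocations,
    update_cluster_centers,
    update_cluster_scales,
    update_local_shrinkage,
    update_subcomponent_covs,
    update_subcomponent_means,
    update_weights,
    run_chain,
    prior_state,
    validation_hyperparams,
)
from helpers import unit_summary  # noqa: F401  (shared helper below)


def scalar_hyper(**overrides):
    from helpers import unit_summary

    return tune_hyperparams(unit_summary(1), K=1, L=1, **overrides)


def one_cluster_state(mu, sigma2, b0=0.0, C0=1.0, lam=1.0):
    """K = L = r = 1 state for scalar conjugacy checks."""
    return MixtureState(
        eta=np.array([1.0]),
        w=np.array([[1.0]]),
        mu=np.array([[[float(mu)]]]),
        Sigma=np.array([[[[float(sigma2)]]]]),
        b0=np.array([[float(b0)]]),
        C0=np.array([[[float(C0)]]]),
        lam=np.array([[float(lam)]]),
    )


class TestAllocations:
    def test_single_component_is_deterministic(self, rng):
        state = one_cluster_state(0.0, 1.0)
        alloc = update_allocations(np.array([[0.3], [5.0]]), state, rng)
        assert np.all(alloc.S == 0) and np.all(alloc.I == 0)
        assert alloc.N_k.tolist() == [2]

    def test_dominant_cluster_takes_all(self, rng):
        state = MixtureState(
            eta=np.array([1.0, 0.0]),
            w=np.ones((2, 1)),
            mu=np.array([[[0.0]], [[50.0]]]),
            Sigma=np.ones((2, 1, 1, 1)),
        )
        alloc = update_allocations(rng.standard_normal((200, 1)), state, rng)
        assert np.all(alloc.S == 0)

    def test_frequencies_match_analytic_responsibilities(self, rng):
        # 2-component 1-D mixture, one observation replicated many times:
        # rows are allocated independently, so the empirical frequencies over
        # the replicates estimate the closed-form posterior responsibilities
        eta = np.array([0.3, 0.7])
        mus = np.array([-1.0, 1.5])
        sig = np.array([1.0, 2.0])
        state = MixtureState(
            eta=eta,
            w=np.ones((2, 1)),
            mu=mus.reshape(2, 1, 1),
            Sigma=sig.reshape(2, 1, 1, 1),
        )
        y0 = 0.4
        n = 100_000
        alloc = update_allocations(np.full((n, 1), y0), state, rng)
        dens = eta * stats.norm.pdf(y0, loc=mus, scale=np.sqrt(sig))
        p1 = dens[0] / dens.sum()
        freq = np.mean(alloc.S == 0)
        se = np.sqrt(p1 * (1 - p1) / n)
        assert abs(freq - p1) < 3 * se

    def test_underflow_guard(self, rng):
        state = one_cluster_state(0.0, 1e-300)
        state.Sigma[0, 0, 0, 0] = 1.0
        state.eta = np.array([0.0])  # impossible: zero total weight
        with pytest.raises(FloatingPointError):
            update_allocations(np.array([[0.0]]), state, rng)


class TestWeights:
    def test_posterior_mean(self, rng):
        h = tune_hyperparams(unit_summary(2), K=3, L=2, e0=0.5)
        N_kl = np.array([[10, 5], [0, 0], [3, 2]])
        alloc = AllocationPair(
            S=np.empty(0), I=np.empty(0), N_k=N_kl.sum(axis=1), N_kl=N_kl
        )
        n = 20000
        etas = np.stack([update_weights(alloc, h, rng)[0] for _ in range(n)])
        expected = (0.5 + N_kl.sum(axis=1)) / (20 + 3 * 0.5)
        se = etas.std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(etas.mean(axis=0) - expected) < 4 * se)

    def test_empty_counts_give_prior_draw(self, rng):
        h = tune_hyperparams(unit_summary(2), K=4, L=2, e0=2.0)
        alloc = AllocationPair(
            S=np.empty(0), I=np.empty(0), N_k=np.zeros(4, int), N_kl=np.zeros((4, 2), int)
        )
        etas = np.stack([update_weights(alloc, h, rng)[0] for _ in range(20000)])
        # symmetric Dirichlet(2) moments
        assert np.allclose(etas.mean(axis=0), 0.25, atol=0.01)
        assert np.allclose(etas.var(axis=0), 0.25 * 0.75 / 9, atol=0.004)


class TestConjugateUpdates:
    def test_mean_update_precision_weighted_formula(self, rng):
        y = np.array([[0.8], [1.2], [1.0], [2.0]])
        sigma2, b0, B0_scalar = 0.5, -1.0, 0.05
        h = scalar_hyper()
        state = one_cluster_state(0.0, sigma2, b0=b0)
        alloc = AllocationPair(
            S=np.zeros(4, np.int32),
            I=np.zeros(4, np.int32),
            N_k=np.array([4]),
            N_kl=np.array([[4]]),
        )
        draws = np.array(
            [
                update_subcomponent_means(y, alloc, state, h, rng)[0, 0, 0]
                for _ in range(8000)
            ]
        )
        prec = 1 / B0_scalar + 4 / sigma2
        mean = (b0 / B0_scalar + y.sum() / sigma2) / prec
        assert draws.mean() == pytest.approx(mean, abs=4 * draws.std() / np.sqrt(8000))
        assert draws.var() == pytest.approx(1 / prec, rel=0.1)

    def test_empty_subcomponent_mean_is_prior_draw(self, rng):
        h = scalar_hyper()
        state = one_cluster_state(0.0, 1.0, b0=3.0)
        alloc = AllocationPair(
            S=np.empty(0, np.int32),
            I=np.empty(0, np.int32),
            N_k=np.array([0]),
            N_kl=np.array([[0]]),
        )
        y = np.empty((0, 1))
        draws = np.array(
            [update_subcomponent_means(y, alloc, state, h, rng)[0, 0, 0] for _ in range(5000)]
        )
        assert draws.mean() == pytest.approx(3.0, abs=0.05)
        assert draws.var() == pytest.approx(0.05, rel=0.15)  # B0 = phi_W(1-phi_B)

    def test_cov_update_matches_quadrature_posterior(self, rng):
        # r = 1: full conditional is inverse-gamma; check its mean against
        # numerically integrating prior x likelihood on a grid
        y = np.array([[0.5], [-0.3], [1.1], [0.2], [-0.8]])
        mu, C0 = 0.1, 0.8
        h = scalar_hyper()
        c0 = h.c0  # 2.5 in one dimension
        state = one_cluster_state(mu, 1.0, C0=C0)
        state = MixtureState(
            eta=state.eta, w=state.w, mu=state.mu, Sigma=state.Sigma,
            b0=state.b0, C0=np.array([[[C0]]]), lam=state.lam,
        )
        alloc = AllocationPair(
            S=np.zeros(5, np.int32),
            I=np.zeros(5, np.int32),
            N_k=np.array([5]),
            N_kl=np.array([[5]]),
        )

        def unnorm(s2):
            prior = s2 ** -(c0 + 1) * np.exp(-C0 / s2)
            lik = s2 ** (-2.5) * np.exp(-np.sum((y - mu) ** 2) / (2 * s2))
            return prior * lik

        norm = quad(unnorm, 1e-6, 60)[0]
        target_mean = quad(lambda s: s * unnorm(s), 1e-6, 60)[0] / norm
        # closed form as cross-check: InvGamma(c0 + n/2, C0 + scatter/2)
        a_post = c0 + 2.5
        b_post = C0 + 0.5 * np.sum((y - mu) ** 2)
        assert target_mean == pytest.approx(b_post / (a_post - 1), rel=1e-6)
        draws = np.array(
            [update_subcomponent_covs(y, alloc, state, h, rng)[0, 0, 0, 0] for _ in range(8000)]
        )
        se = draws.std() / np.sqrt(8000)
        assert draws.mean() == pytest.approx(target_mean, abs=4 * se)

    def test_center_update_flat_prior_limit(self, rng):
        # M0 -> infinity: posterior mean is the average of the subcomponent means
        h = HyperParams(
            K=1, L=3, e0=0.001, d0=4.0, c0=2.5, g0=0.5,
            G0=np.eye(1), B0=np.array([[0.2]]), m0=np.array([50.0]),
            M0=np.array([[1e8]]), nu=10.0,
        ).validate()
        mus = np.array([[-1.0], [0.5], [2.0]])
        state = MixtureState(
            eta=np.array([1.0]), w=np.full((1, 3), 1 / 3),
            mu=mus[None, :, :], Sigma=np.ones((1, 3, 1, 1)),
            b0=np.array([[0.0]]), C0=np.ones((1, 1, 1)), lam=np.ones((1, 1)),
        )
        draws = np.array(
            [update_cluster_centers(state, h, rng)[0, 0] for _ in range(5000)]
        )
        assert draws.mean() == pytest.approx(mus.mean(), abs=0.02)
        assert draws.var() == pytest.approx(0.2 / 3, rel=0.15)

    def test_scale_update_fixed_variant_and_quadrature(self, rng):
        h = scalar_hyper(fix_C0=True)
        state = one_cluster_state(0.0, 0.7)
        fixed = update_cluster_scales(state, h, rng)
        assert np.allclose(fixed, h.g0 * np.linalg.inv(h.G0))
        # r = 1 quadrature check of the Wishart full conditional
        h2 = scalar_hyper()
        g0, G0 = h2.g0, h2.G0[0, 0]
        c0, sig = h2.c0, 0.7

        def unnorm(c):
            prior = c ** (g0 - 1) * np.exp(-G0 * c)
            lik = c**c0 * np.exp(-c / sig)  # IW(c0, c) normalizer x kernel in c
            return prior * lik

        norm = quad(unnorm, 0, 200)[0]
        target_mean = quad(lambda c: c * unnorm(c), 0, 200)[0] / norm
        draws = np.array(
            [update_cluster_scales(state, h2, rng)[0, 0, 0] for _ in range(8000)]
        )
        se = draws.std() / np.sqrt(8000)
        assert draws.mean() == pytest.approx(target_mean, abs=4 * se)

    def test_shrinkage_update_matches_quadrature(self, rng):
        # lambda full conditional ~ lambda^(nu-1) e^{-nu lambda} x
        # prod_l N(mu_l; b0, lambda B0)
        h = scalar_hyper()  # nu = 10, B0 = 0.05
        nu, B0 = h.nu, h.B0[0, 0]
        mus = np.array([0.3, -0.2])
        L = 2
        h2 = tune_hyperparams(unit_summary(1), K=1, L=L)
        state = MixtureState(
            eta=np.array([1.0]), w=np.full((1, L), 0.5),
            mu=mus.reshape(1, L, 1), Sigma=np.ones((1, L, 1, 1)),
            b0=np.array([[0.0]]), C0=np.ones((1, 1, 1)), lam=np.ones((1, 1)),
        )

        def unnorm(lam):
            prior = lam ** (nu - 1) * np.exp(-nu * lam)
            lik = lam ** (-L / 2) * np.exp(-np.sum(mus**2) / (2 * lam * B0))
            return prior * lik

        norm = quad(unnorm, 1e-9, 60)[0]
        target_mean = quad(lambda x: x * unnorm(x), 1e-9, 60)[0] / norm
        draws = np.array(
            [update_local_shrinkage(state, h2, rng)[0, 0] for _ in range(8000)]
        )
        se = draws.std() / np.sqrt(8000)
        assert draws.mean() == pytest.approx(target_mean, abs=4 * se)

    def test_shrinkage_fixed_variant(self, rng):
        h = tune_hyperparams(unit_summary(2), K=2, L=2, fix_lambda=True)
        state = prior_state(h, rng)
        assert np.all(update_local_shrinkage(state, h, rng) == 1.0)

    def test_shrinkage_gamma_limit_when_b_zero(self, rng):
        # all subcomponent means at the cluster center: conditional becomes
        # Gamma(nu - L/2, nu)
        h = tune_hyperparams(unit_summary(1), K=1, L=2)
        state = MixtureState(
            eta=np.array([1.0]), w=np.full((1, 2), 0.5),
            mu=np.zeros((1, 2, 1)), Sigma=np.ones((1, 2, 1, 1)),
            b0=np.zeros((1, 1)), C0=np.ones((1, 1, 1)), lam=np.ones((1, 1)),
        )
        draws = np.array(
            [update_local_shrinkage(state, h, rng)[0, 0] for _ in range(20000)]
        )
        p = h.nu - 1.0
        ks = stats.kstest(draws, stats.gamma(a=p, scale=1 / h.nu).cdf)
        assert ks.pvalue > 0.01


class TestRunChain:
    def test_deterministic_given_seed(self, rng):
        y = rng.standard_normal((60, 2))
        h = tune_hyperparams(unit_summary(2), K=4, L=2)
        d1 = run_chain(y, h, n_iter=25, burnin=25, seed=7)
        d2 = run_chain(y, h, n_iter=25, burnin=25, seed=7)
        for f in ("eta", "mu", "Sigma", "S", "lam", "K0_per_draw"):
            assert np.array_equal(getattr(d1, f), getattr(d2, f))
        d3 = run_chain(y, h, n_iter=25, burnin=25, seed=8)
        assert not np.array_equal(d1.eta, d3.eta)

    def test_counts_consistent_and_meta(self, rng):
        y = rng.standard_normal((50, 2))
        h = tune_hyperparams(unit_summary(2), K=3, L=2)
        d = run_chain(y, h, n_iter=10, burnin=5, seed=1)
        assert d.n_draws == 10
        for m in range(10):
            assert d.K0_per_draw[m] == len(np.unique(d.S[m]))
        assert d.meta["burnin"] == 5 and d.meta["seed"] == 1

    def test_invalid_arguments_raise(self, rng):
        h = tune_hyperparams(unit_summary(2), K=3, L=2)
        with pytest.raises(ValueError):
            run_chain(np.ones((10, 2)) * np.nan, h, 5, 5, seed=0)
        with pytest.raises(ValueError):
            run_chain(np.random.default_rng(0).standard_normal((10, 2)), h, 0, 5, seed=0)

    def test_subcomponents_fill_within_largest_cluster(self, rng):
        # d0 = d/2 + 2 keeps all L subcomponents of a populated cluster busy
        from sparsemixmix.synthetic import SyntheticSpec, gen_mixmix
        from sparsemixmix.hyperprior import summarize_data

        data, _, _ = gen_mixmix(SyntheticSpec(n_obs=400, n_clusters=2, seed=5))
        h = tune_hyperparams(summarize_data(data), K=5, L=3)
        d = run_chain(data, h, n_iter=300, burnin=300, seed=2)
        filled = 0
        for m in range(d.n_draws):
            counts = np.bincount(d.S[m], minlength=5)
            k_big = int(np.argmax(counts))
            sub = np.unique(d.I[m][d.S[m] == k_big])
            filled += len(sub) == 3
        assert filled / d.n_draws >= 0.9
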
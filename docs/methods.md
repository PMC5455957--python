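# Methods

This note documents the model, the numerical choices, and what the test
suite does and does not establish.

## Model and conventions

The data model is the two-level mixture described in the README: an
overfitting upper level with K cluster densities, each a mixture of L
multivariate Gaussian subcomponents. All matrix-variate distributions use a
single rate-matrix convention (`sparsemixmix/_wishart.py`):

* Wishart `W(g, G)`: density ∝ |C|^(g−(r+1)/2) exp(−tr(G C)),
  E[C] = g G⁻¹ (= textbook Wishart with df 2g, scale (2G)⁻¹);
* inverse Wishart `IW(c, C)`: density ∝ |S|^(−c−(r+1)/2) exp(−tr(C S⁻¹)),
  E[S] = C / (c − (r+1)/2) (= textbook inverse Wishart with df 2c, scale 2C).

This convention is forced by the fixed-scale variant, which pins
C0k = g0·G0⁻¹, i.e. at the Wishart prior mean. Every conjugate update and
the prior-calibration Monte Carlo test are consistent with it; the test
suite cross-checks the samplers against scipy's gamma/inverse-gamma in one
dimension and against analytic means in general dimension.

## Hyperparameter tuning

Given the per-dimension sample variances diag(S_y) and user fractions
φ_B, φ_W ∈ (0,1):

* B0 = φ_W (1−φ_B) Diag(diag S_y) — covariance of subcomponent means
  around the cluster center (with the shrinkage factors λ integrated out,
  since E[λ] = 1);
* G0 = g0 / [(c0 − (r+1)/2)(1−φ_B)(1−φ_W)] · Diag(diag S_y)⁻¹ — solved
  from E[Σ_kl] = E[C0k]/(c0−(r+1)/2) = (1−φ_B)(1−φ_W) Diag(diag S_y);
* c0 = 2.5 + (r−1)/2 (keeps Σ_kl eigenvalues away from zero while allowing
  large spread), g0 = 0.5 + (r−1)/2 (regularity of the Wishart),
  m0 = per-dimension midpoint of the data range, M0 = 10 S_y (nearly flat
  prior on cluster centers), ν = 10 (≈90% prior mass of λ in [0.5, 1.5],
  so only mild per-dimension adaptation of B0).

Only the diagonal of S_y enters B0 and G0, so near-singular sample
covariances are tolerated; a zero diagonal entry (constant column) is an
error. Defaults φ_B = 0.5, φ_W = 0.1: deliberately *not* maximal
separation, so that enough variance is left over for wide, overlapping
subcomponents — tight subcomponents are exactly what the prior is designed
to avoid.

The Dirichlet concentrations use d = r + r(r+1)/2, the free-parameter count
of one Gaussian subcomponent: e0 = 0.001 ≪ d/2 on cluster weights (the
asymptotic condition for superfluous components to empty), d0 = d/2 + 2 >
d/2 on subcomponent weights (the condition for overfitted components to
fill by splitting). The theory behind these thresholds speaks of the
dimension of the component-specific parameter; applying it at the level of
one subcomponent is this package's reading for the lower level, and e0 is
so far below any plausible d/2 that the choice of d is immaterial there.

## Gibbs sampler

One sweep updates, in fixed order: (1) the indicator pairs (S_i, I_i)
jointly from the K·L-cell categorical (log space, Gumbel-max); (2) η and
the w_k from their Dirichlet conditionals; (3) subcomponent means (normal);
(4) subcomponent covariances (inverse Wishart); (5) cluster centers
(normal, with the L subcomponent means as pseudo-observations); (6) cluster
scales C0k (Wishart with shape g0 + L c0 and rate G0 + Σ_l Σ_kl⁻¹); (7)
shrinkage factors λ_kj from GIG(ν − L/2, 2ν, Σ_l (μ_klj − b0kj)²/B0_jj).
Sweep order is irrelevant for correctness; this order simply follows the
hierarchy. Empty clusters and subcomponents are refreshed from the prior,
which is what keeps emptied clusters available should the data demand them.

Numerical choices:

* all density evaluations are Cholesky-based and log-stable; an observation
  whose K·L log-probabilities all underflow raises rather than silently
  misallocating;
* covariance draws are symmetrized as (A + Aᵀ)/2;
* Dirichlet draws guard against total gamma underflow at e0 = 0.001 by
  falling back to a uniformly random vertex (the correct limit);
* GIG draws use a vectorized ratio-of-uniforms sampler (`_gig.py`) with the
  accept test evaluated relative to the density mode; for p < 1 or
  pathological tails it defers to scipy's generator, and when the quadratic
  coefficient underflows (b < 1e-300) with p > 0 the Gamma(p, ν) limit is
  used;
* initialization partitions the data by k-means into K groups (configurable
  to uniform-random), assigns subcomponents uniformly, draws cluster-level
  hyperparameters from the prior and completes one parameter sweep
  conditional on those allocations — a warm start that shortens burn-in
  without touching the stationary distribution;
* a single seeded numpy Generator is threaded through every update in sweep
  order, so chains are bit-reproducible given the seed.

No identifiability constraint is imposed during sampling. Defaults are 4000
retained iterations after 4000 burn-in.

### Sampler validation

The successive-conditional ("getting it right") simulator alternates
re-simulating the data given the current augmented state with one full
Gibbs sweep; the stationary marginal over parameters is then exactly the
prior, so chain moments of η, λ and b0 are compared against analytic prior
moments with batch-means standard errors. The validation instance
(`validation_hyperparams`) uses balanced scales (M0 = I, B0 = I/2, prior
mean of Σ_kl = I, e0 = 0.5): with the data-analysis defaults (e0 = 0.001,
M0 = 10 S_y ≫ B0) the validation chain's autocorrelation time for b0 and η
exceeds any reasonable batch length, so moment z-scores would measure
mixing, not correctness. The same update code paths are exercised either
way; at 10⁴ sweeps all |z| ≲ 2.

## Post-processing

K̂0 is the mode of the per-draw nonempty-cluster counts, ties broken toward
fewer clusters (parsimony). Conditional on K̂0, draws with exactly K̂0
nonempty clusters are relabeled in the point-process representation: the
functional clustered across draws is the cluster moment mean
μ̃_k = Σ_l w_kl μ_kl, which is invariant under subcomponent relabeling —
necessary because lower-level label switching is deliberately ignored.
K-means (seeded; initialized at the first selected draw's functionals, with
a multi-restart backup) assigns each draw's clusters to reference labels;
draws that do not map one-to-one are dropped, and the retained fraction is
reported as the permutation rate. The MAP partition takes per-observation
majority labels (ties to the smaller label); the co-clustering similarity
matrix Pr{S_i = S_j | y} is computed from all draws since it is
label-invariant. External validation uses the adjusted Rand index and the
misclassification rate under the optimal (Hungarian) label matching.

## Partition prior

`partition_prior` computes the exact assignment/partition priors induced by
the sparse Dirichlet weights, their predictive rules, and DP/PYP
comparators, all in log-gamma arithmetic. Expected-cluster-count curves use
the fact that K0 evolves as a Markov chain under the sequential predictive
rules; the forward recursion is exact for the sparse mixture (hard cap K)
and truncated with an absorbing top state for DP/PYP. Enumeration oracles
(normalization, equivalence-class sums, total-variation distances) are kept
at desk scale, N ≤ 6.

## Synthetic data

The generators enforce the variance fractions on the *generating
parameters*, not on finite samples: cluster centers sit at regular-simplex
(or, for K > r+1 in the plane, regular-polygon) vertices scaled
analytically so the implied between-cluster trace fraction equals
φ_B exactly, and subcomponent means are spread the same way within clusters
to hit φ_W exactly; round-trips through `variance_decomposition` are tested
to 1e-10. Defaults: 4 clusters of 2 subcomponents in r = 2,
φ_B_target = 0.9, φ_W_target = 0.1. The φ_B default encodes the cluster
concept the method targets — dense clusters with clear gaps between them
(at φ_B = 0.5 the Bayes-optimal partition itself misclassifies on the
order of 10% of points for four planar clusters, so no method could score
near-perfect recovery there). Fits in the tests nevertheless use the
standard prior fractions φ_B = 0.5, φ_W = 0.1, so recovery is demonstrated
under prior/data mismatch, as in practice.

The comet-shaped generator (`gen_sal_like`) adds an exponential radial
factor along a random axis plus isotropic noise — a qualitative stand-in
for shifted-asymmetric-Laplace clusters (skewness > 1 along the axis). It
is a stress regime: the default prior is *not* expected to capture such
nondense clusters, which is why the fixed-scale variant exists.

What passing tests do not show: the generators produce well-conditioned,
moderately-dimensional data without outliers, missingness or ties; real
data with strong tails or high dimension may mix more slowly and may need
the fixed-scale variant, longer chains, or different φ fractions.

## Problem sizes in the test suite

Chosen so the whole suite and the acceptance script each run in a few
minutes on one core: recovery uses N = 800, K = 10, L = 4 with 2000
retained iterations after 2000 burn-in across 10 seeds; the emptying check
uses N = 500 at the same chain length; sampler validation uses 10⁴ sweeps
on N = 10; prior calibration uses 10⁵ replicates; enumeration checks stay
at N ≤ 6. These sizes are the package's reference benchmark settings, and
the measured quantities (ARI ≈ 0.99, calibration ratios ≈ 1, |z| ≲ 2) are
already stable at them.

## Known limitations

* L is fixed, not inferred; the guidance is to choose it generously but
  small (4–5 for benchmark-scale data, more for very complex shapes).
* No collapsed or split-merge sampler: mixing on large, high-dimensional
  data relies on the blocked conditional sweeps alone.
* The shrinkage-factor update requires a diagonal B0 (the tuned B0 always
  is; a non-diagonal override with λ updates enabled raises).
* Marginal-likelihood model selection is intentionally absent: the number
  of clusters comes from the K0 posterior, conditional on a sufficiently
  large K.
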
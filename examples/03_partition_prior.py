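"""The clustering prior induced by sparse weights, against DP / Pitman-Yor.

Integrating out the sparse Dirichlet weights gives an exact prior over
partitions.  Its predictive rule for opening a new cluster *decreases* as
clusters fill up and the expected number of clusters stays bounded by K as
the sample grows — unlike the Chinese restaurant process (constant rate,
E[K0] ~ alpha log N) or the Pitman-Yor process (increasing rate, power law).
With e0 = alpha/K the sparse prior converges to the CRP as K grows.
"""

import numpy as np

from sparsemixmix import (
    PartitionPriorSpec,
    crp_predictive,
    expected_K0,
    predictive_new,
    tv_distance_to_crp,
)

spec = PartitionPriorSpec(K=10, e0=0.1, N=100, alpha=1.0, beta=0.0)
print("probability that observation 100 opens a new cluster:")
for k0 in (1, 3, 6, 9):
    sparse = predictive_new(k0, spec)
    _, crp = crp_predictive(0, k0, spec)
    print(f"  {k0} clusters occupied: sparse mixture {sparse:.4f}   CRP {crp:.4f}")

grid = [10, 100, 1000, 10000]
sparse_curve = expected_K0(spec, grid, "sparse")
dp_curve = expected_K0(spec, grid, "dp")
print("\nexpected number of occupied clusters E[K0]:")
print("  N        :", grid)
print("  sparse   :", np.round(sparse_curve, 2), " (bounded by K=10)")
print("  DP       :", np.round(dp_curve, 2), " (~ alpha log N, unbounded)")

print("\nTV distance to the CRP prior on partitions of N=5, with e0 = alpha/K:")
for K in (5, 10, 50, 500):
    print(f"  K={K:4d}: {tv_distance_to_crp(5, K, 1.0 / K, 1.0):.5f}")
# the shrinking distance is the finite-K mixture converging to a DP mixture
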
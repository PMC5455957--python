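import numpy as np

from sparsemixmix.hyperprior import DataSummary


def unit_summary(r: int = 2) -> DataSummary:
    """A unit-scale data summary for constructing hyperparameters directly."""
    return DataSummary(
        n_obs=100,
        n_dims=r,
        midpoint=np.zeros(r),
        sample_cov=np.eye(r),
        sample_cov_diag=np.ones(r),
    )
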
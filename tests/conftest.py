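import numpy as np
import pytest

from sparsemixmix.model import MixtureState


def make_random_state(K: int, L: int, r: int, rng: np.random.Generator) -> MixtureState:
    """A random valid mixture state with well-conditioned covariances."""
    eta = rng.dirichlet(np.full(K, 2.0))
    w = rng.dirichlet(np.full(L, 2.0), size=K)
    mu = rng.normal(scale=3.0, size=(K, L, r))
    A = rng.standard_normal((K, L, r, r))
    Sigma = A @ np.swapaxes(A, -1, -2) + 0.5 * np.eye(r)
    return MixtureState(eta=eta, w=w, mu=mu, Sigma=Sigma).validate()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
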
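"""Batched Wishart / inverse-Wishart samplers in the rate-matrix convention.

All matrix-variate distributions in this package use a single convention:

* ``W(g, G)`` has density proportional to ``|C|^(g-(r+1)/2) exp(-tr(G C))``
  and expectation ``E[C] = g * G^{-1}``; it equals the textbook Wishart with
  ``df = 2g`` and scale ``(2G)^{-1}``.
* ``IW(c, C)`` has density proportional to
  ``|S|^{-(c+(r+1)/2)} exp(-tr(C S^{-1}))`` and expectation
  ``E[S] = C / (c - (r+1)/2)``; it equals the textbook inverse Wishart with
  ``df = 2c`` and scale ``2C``.

Samplers use the Bartlett decomposition and are batched over a leading axis,
which keeps the Gibbs sweep free of per-component ``scipy.stats`` call
overhead.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sample_wishart", "sample_invwishart"]


def _bartlett_factors(df, n: int, r: int, rng: np.random.Generator) -> np.ndarray:
    """Lower-triangular Bartlett factors A with A A^T ~ W_std(df, I), shape (n, r, r).

    ``df`` may be a scalar or an (n,) array of per-draw degrees of freedom.
    """
    df = np.broadcast_to(np.asarray(df, dtype=float), (n,))
    if np.any(df <= r - 1):
        raise ValueError(f"Wishart degrees of freedom 2*shape must exceed r-1={r - 1}")
    A = np.zeros((n, r, r))
    idx = np.arange(r)
    A[:, idx, idx] = np.sqrt(rng.chisquare(df[:, None] - idx[None, :], size=(n, r)))
    if r > 1:
        tril = np.tril_indices(r, k=-1)
        A[:, tril[0], tril[1]] = rng.standard_normal((n, len(tril[0])))
    return A


def sample_wishart(g, G: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` matrices from W(g, G), rate convention, E = g * G^{-1}.

    ``g`` may be a scalar or (n,) array; G a single (r, r) matrix or a batch
    (n, r, r).
    """
    G = np.asarray(G, dtype=float)
    r = G.shape[-1]
    # W(g, G) = W_std(2g, (2G)^{-1}); chol of the standard scale matrix
    scale = np.linalg.inv(2.0 * G)
    scale = 0.5 * (scale + np.swapaxes(scale, -1, -2))
    L = np.linalg.cholesky(np.broadcast_to(scale, (n, r, r)))
    A = _bartlett_factors(2.0 * np.asarray(g, dtype=float), n, r, rng)
    LA = L @ A
    W = LA @ np.swapaxes(LA, -1, -2)
    return 0.5 * (W + np.swapaxes(W, -1, -2))


def sample_invwishart(c, C: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` matrices from IW(c, C), E = C / (c - (r+1)/2).

    ``c`` may be a scalar or (n,) array; C a single (r, r) matrix or a batch
    (n, r, r).
    """
    C = np.asarray(C, dtype=float)
    r = C.shape[-1]
    # S ~ IW(c, C)  <=>  S^{-1} ~ W(c, C) in the rate convention
    precision = sample_wishart(c, C, n, rng)
    S = np.linalg.inv(precision)
    return 0.5 * (S + np.swapaxes(S, -1, -2))
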
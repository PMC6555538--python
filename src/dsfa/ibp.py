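"""Finite-truncation Indian buffet process prior and its MRF modification.

The IBP is approximated by its standard finite pre-limit construction with
``k_max`` columns::

    v_k  ~ Beta(alpha / k_max, 1)
    Z_dk ~ Bernoulli(v_k)

As k_max grows this converges to the IBP, under which the expected number of
non-empty columns is alpha * H_D (the D-th harmonic number).  An optional
Markov random field multiplies the prior of each column by
exp(sum_{(d',d) in edges} w_{d'd} Z_{d'k} Z_{dk}), encouraging related drugs
to share latent characteristics.
"""

from __future__ import annotations

import numpy as np

from .model import Hyperparams, LatentState, RelationGraph


def sample_finite_ibp(
    D: int, hp: Hyperparams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (v, Z) from the finite-truncation IBP prior.

    Returns ``v`` of shape (k_max,) and binary ``Z`` of shape (D, k_max).
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    v = rng.beta(hp.alpha / hp.k_max, 1.0, size=hp.k_max)
    Z = (rng.random((D, hp.k_max)) < v[None, :]).astype(np.int8)
    return v, Z


def mrf_column_log_prior(
    z_col: np.ndarray, v_k: float, graph: RelationGraph | None
) -> float:
    """Unnormalized log prior of one binary column under the MRF-coupled IBP.

    Sum of the pairwise MRF terms and the independent Bernoulli(v_k) terms;
    the column-wise partition function is never computed (only differences
    are used downstream).
    """
    if not 0.0 < v_k < 1.0:
        raise ValueError("v_k must lie in (0, 1)")
    z = np.asarray(z_col, dtype=float)
    lp = float(np.sum(z * np.log(v_k) + (1.0 - z) * np.log1p(-v_k)))
    if graph is not None:
        if graph.n_nodes != z.size:
            raise ValueError("graph size mismatch")
        for i, j, w in graph.edges:
            lp += w * z[i] * z[j]
    return lp


def prior_logodds_zdk(
    d: int, k: int, state: LatentState, graph: RelationGraph | None = None
) -> float:
    """Prior log-odds of Z_dk = 1 given the rest of its column.

    log(v_k / (1 - v_k)) plus the sum of edge weights to neighbours whose
    entry in column k is active.  This is the prior part of the Gibbs flip
    log-odds for the loadings update.
    """
    v_k = float(state.v[k])
    lo = float(np.log(v_k) - np.log1p(-v_k))
    if graph is not None:
        for i, j, w in graph.edges:
            if i == d:
                lo += w * float(state.Z[j, k])
            elif j == d:
                lo += w * float(state.Z[i, k])
    return lo


def expected_active_columns_ibp(D: int, alpha: float) -> float:
    """IBP-limit expected number of non-empty columns: alpha * H_D."""
    return alpha * float(np.sum(1.0 / np.arange(1, D + 1)))
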
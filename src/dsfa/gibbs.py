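"""Gibbs sampler: full conditional updates for every unknown and the driver.

All updates are standard conjugate or spike-and-slab moves:

* ``Z``/``G`` and ``V``/``B`` — the binary indicator is resampled with the
  coefficient analytically integrated out (slab N(0,1) against the point
  mass), then the coefficient is redrawn from its Gaussian conditional.
* ``X`` — exact multivariate Gaussian conditional per cell line, coupling
  the sensitivity likelihood and the feature regression.
* ``v``, ``pi`` — conjugate Beta updates (unaffected by the MRF terms,
  which involve only the binary matrices).
* ``lam_y``, ``lam_x``, ``b_y``, ``b_x`` — conjugate Gamma updates under the
  shape/scale reading of the hierarchical noise prior.

Masked (unobserved) entries of Y contribute to no sufficient statistic; the
diagonal noise makes the likelihood factorize over entries, so this is exact.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import expit

from .model import (
    FeatureMatrix,
    GibbsConfig,
    Hyperparams,
    LatentState,
    PosteriorTrace,
    RelationGraph,
    SensitivityMatrix,
    Standardizer,
    log_joint,
)

logger = logging.getLogger(__name__)

_EPS = 1e-12


def _clip_unit(x: np.ndarray) -> np.ndarray:
    return np.clip(x, _EPS, 1.0 - _EPS)


def spike_slab_conditional(
    resid: np.ndarray, x: np.ndarray, prec: float, prior_logodds: float
) -> tuple[float, float, float]:
    """Single-coefficient spike-and-slab full conditional.

    For the model resid_n = c * x_n + noise(1/prec) with slab c ~ N(0, 1)
    against the point mass c = 0, returns (p_active, slab posterior mean,
    slab posterior variance).  The log Bayes factor of slab against spike is
    A^2 / (2 s) - log(s) / 2 with A = prec * sum(x * resid) and
    s = 1 + prec * sum(x^2).
    """
    A = prec * float(x @ resid)
    s = 1.0 + prec * float(x @ x)
    log_bf = 0.5 * A * A / s - 0.5 * np.log(s)
    p1 = float(expit(prior_logodds + log_bf))
    return p1, A / s, 1.0 / s


# ---------------------------------------------------------------------------
# loadings (Z, G)
# ---------------------------------------------------------------------------

def update_loadings(
    state: LatentState,
    Y: SensitivityMatrix,
    drug_graph: RelationGraph | None = None,
    rng: np.random.Generator | None = None,
) -> LatentState:
    """Resample (Z_dk, G_dk) for every drug d and LC k.

    Without a drug graph the D entries of a column are conditionally
    independent and updated in a vectorized block; with MRF coupling they
    are scanned sequentially within each column.
    """
    rng = rng if rng is not None else np.random.default_rng()
    Yv = np.where(Y.observed_mask, Y.values, 0.0)
    M = Y.observed_mask.astype(float)
    D, K = state.Z.shape
    lam = state.lam_y
    W = drug_graph.weight_matrix() if drug_graph is not None else None

    R = (Yv - state.G @ state.X) * M  # masked residual, maintained per column
    for k in range(K):
        xk = state.X[k]
        rk = R + np.outer(state.G[:, k], xk) * M
        Sxx = M @ (xk * xk)                  # per-drug sum of x^2 over observed
        Sxr = rk @ xk                        # rk already masked
        A = lam * Sxr
        s = 1.0 + lam * Sxx
        log_bf = 0.5 * A * A / s - 0.5 * np.log(s)
        v_k = float(state.v[k])
        base_lo = float(np.log(v_k) - np.log1p(-v_k))
        if W is None:
            p1 = expit(base_lo + log_bf)
            z = (rng.random(D) < p1).astype(np.int8)
            g = np.where(z == 1, A / s + rng.standard_normal(D) / np.sqrt(s), 0.0)
            state.Z[:, k] = z
            state.G[:, k] = g
        else:
            for d in range(D):
                lo = base_lo + float(W[d] @ state.Z[:, k]) + log_bf[d]
                z_d = np.int8(rng.random() < expit(lo))
                state.Z[d, k] = z_d
                state.G[d, k] = (
                    A[d] / s[d] + rng.standard_normal() / np.sqrt(s[d])
                    if z_d
                    else 0.0
                )
        R = rk - np.outer(state.G[:, k], xk) * M
    return state


# ---------------------------------------------------------------------------
# feature regression (V, B)
# ---------------------------------------------------------------------------

def update_regression(
    state: LatentState,
    F: FeatureMatrix,
    feat_graph: RelationGraph | None = None,
    rng: np.random.Generator | None = None,
) -> LatentState:
    """Resample (V_kp, B_kp) for every LC k and feature p.

    Features are scanned sequentially (their conditionals are coupled
    through the row residual and, when present, the gene MRF); the K rows
    are conditionally independent and updated as a block for each feature.
    """
    rng = rng if rng is not None else np.random.default_rng()
    Fv = F.values
    K, P = state.V.shape
    lam = state.lam_x
    Wf = feat_graph.weight_matrix() if feat_graph is not None else None
    Sff = np.einsum("pn,pn->p", Fv, Fv)

    Rx = state.X - state.B @ Fv  # K x N row residuals, maintained per feature
    logit_pi = np.log(state.pi) - np.log1p(-state.pi)
    for p in range(P):
        fp = Fv[p]
        r = Rx + np.outer(state.B[:, p], fp)
        A = lam * (r @ fp)
        s = 1.0 + lam * Sff[p]
        log_bf = 0.5 * A * A / s - 0.5 * np.log(s)
        lo = logit_pi[p] + log_bf
        if Wf is not None:
            lo = lo + state.V.astype(float) @ Wf[:, p]
        p1 = expit(lo)
        v_new = (rng.random(K) < p1).astype(np.int8)
        b_new = np.where(v_new == 1, A / s + rng.standard_normal(K) / np.sqrt(s), 0.0)
        state.V[:, p] = v_new
        state.B[:, p] = b_new
        Rx = r - np.outer(b_new, fp)
    return state


# ---------------------------------------------------------------------------
# latent characteristics X
# ---------------------------------------------------------------------------

def latent_conditional(
    y_col: np.ndarray,
    mask_col: np.ndarray,
    f_col_pred: np.ndarray,
    G: np.ndarray,
    lam_y: np.ndarray,
    lam_x: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of one column X_.n given everything else.

    ``f_col_pred`` is (B F)_.n, the regression-side prior mean for the
    column.  Precision is diag(lam_x) + G' diag(lam_y * mask) G.
    """
    w = lam_y * mask_col
    prec = np.diag(lam_x) + (G * w[:, None]).T @ G
    rhs = G.T @ (w * np.where(mask_col > 0, y_col, 0.0)) + lam_x * f_col_pred
    cov = np.linalg.inv(prec)
    return cov @ rhs, cov


def update_latent(
    state: LatentState,
    Y: SensitivityMatrix,
    F: FeatureMatrix,
    rng: np.random.Generator | None = None,
) -> LatentState:
    """Resample every column of X from its exact Gaussian conditional."""
    rng = rng if rng is not None else np.random.default_rng()
    K, N = state.X.shape
    G = state.G
    BF = state.B @ F.values
    lam_x, lam_y = state.lam_x, state.lam_y
    mask = Y.observed_mask
    noise = rng.standard_normal((K, N))
    if mask.all():
        prec = np.diag(lam_x) + (G * lam_y[:, None]).T @ G
        rhs = G.T @ (lam_y[:, None] * Y.values) + lam_x[:, None] * BF
        c, low = cho_factor(prec, lower=True)
        mean = cho_solve((c, low), rhs)
        # x = mean + L^{-T} eps has covariance prec^{-1}
        state.X = mean + solve_triangular(c, noise, trans="T", lower=True)
    else:
        Yv = np.where(mask, Y.values, 0.0)
        for n in range(N):
            w = lam_y * mask[:, n]
            prec = np.diag(lam_x) + (G * w[:, None]).T @ G
            rhs = G.T @ (w * Yv[:, n]) + lam_x * BF[:, n]
            L = np.linalg.cholesky(prec)
            mean = cho_solve((L, True), rhs)
            state.X[:, n] = mean + solve_triangular(L, noise[:, n], trans="T", lower=True)
    return state


# ---------------------------------------------------------------------------
# sparsity rates (v, pi)
# ---------------------------------------------------------------------------

def update_sparsity(
    state: LatentState, rng: np.random.Generator | None = None
) -> LatentState:
    """Conjugate Beta updates for the column rates v and feature rates pi."""
    rng = rng if rng is not None else np.random.default_rng()
    hp = state.hyper
    D, K = state.Z.shape
    P = state.V.shape[1]
    m = state.Z.sum(axis=0)
    state.v = _clip_unit(rng.beta(hp.alpha / hp.k_max + m, 1.0 + D - m))
    c = state.V.sum(axis=0)
    state.pi = _clip_unit(rng.beta(hp.beta / P + c, 1.0 + K - c))
    return state


# ---------------------------------------------------------------------------
# noise precisions
# ---------------------------------------------------------------------------

def gamma_noise_posterior(
    rss: np.ndarray, n_obs: np.ndarray, b: float
) -> tuple[np.ndarray, np.ndarray]:
    """(shape, rate) of the Gamma conditional for a noise precision given its
    residual sum of squares and observation count."""
    return 1.0 + np.asarray(n_obs) / 2.0, b + np.asarray(rss) / 2.0


def update_noise(
    state: LatentState,
    Y: SensitivityMatrix,
    F: FeatureMatrix,
    rng: np.random.Generator | None = None,
) -> LatentState:
    """Conjugate Gamma updates for lam_y, b_y, lam_x, b_x."""
    rng = rng if rng is not None else np.random.default_rng()
    mask = Y.observed_mask
    resid_y = np.where(mask, Y.values - state.G @ state.X, 0.0)
    rss_y = np.einsum("dn,dn->d", resid_y, resid_y)
    n_d = mask.sum(axis=1)
    # precisions and rate hyperparameters are kept in a wide finite band so
    # the prior-only random walk (no-data case) cannot reach inf/0
    lo, hi = 1e-100, 1e100
    shape, rate = gamma_noise_posterior(rss_y, n_d, state.b_y)
    state.lam_y = np.clip(rng.gamma(shape, 1.0 / rate), lo, hi)
    D = state.n_drugs
    state.b_y = float(np.clip(rng.gamma(1.0 + D, 1.0 / (1.0 + state.lam_y.sum())), lo, hi))

    resid_x = state.X - state.B @ F.values
    rss_x = np.einsum("kn,kn->k", resid_x, resid_x)
    N = state.X.shape[1]
    K = state.K
    shape, rate = gamma_noise_posterior(rss_x, np.full(K, N), state.b_x)
    state.lam_x = np.clip(rng.gamma(shape, 1.0 / rate), lo, hi)
    state.b_x = float(np.clip(rng.gamma(1.0 + K, 1.0 / (1.0 + state.lam_x.sum())), lo, hi))
    return state


# ---------------------------------------------------------------------------
# initialization and prior simulation
# ---------------------------------------------------------------------------

def initial_state(
    D: int,
    N: int,
    P: int,
    hp: Hyperparams,
    Fv: np.ndarray,
    rng: np.random.Generator,
) -> LatentState:
    """Over-dispersed start: supports and coefficients from their priors,
    X from its regression prior, all precisions at 1."""
    hp = hp.resolved(P)
    K = hp.k_max
    v = _clip_unit(rng.beta(hp.alpha / K, 1.0, size=K))
    Z = (rng.random((D, K)) < v[None, :]).astype(np.int8)
    G = np.where(Z == 1, rng.standard_normal((D, K)), 0.0)
    pi = _clip_unit(rng.beta(hp.beta / P, 1.0, size=P))
    V = (rng.random((K, P)) < pi[None, :]).astype(np.int8)
    B = np.where(V == 1, rng.standard_normal((K, P)), 0.0)
    X = B @ Fv + rng.standard_normal((K, N))
    return LatentState(
        Z=Z, G=G, v=v, X=X, V=V, B=B, pi=pi,
        lam_y=np.ones(D), b_y=1.0, lam_x=np.ones(K), b_x=1.0, hyper=hp,
    )


def sample_state_from_prior(
    D: int,
    N: int,
    P: int,
    hp: Hyperparams,
    Fv: np.ndarray,
    rng: np.random.Generator,
) -> LatentState:
    """Full forward draw from the prior, including the hierarchical noise."""
    st = initial_state(D, N, P, hp, Fv, rng)
    st.b_y = float(rng.exponential(1.0))
    st.lam_y = rng.exponential(1.0 / st.b_y, size=D)
    st.b_x = float(rng.exponential(1.0))
    st.lam_x = rng.exponential(1.0 / st.b_x, size=hp.k_max)
    # redraw X at the freshly drawn precision
    st.X = st.B @ Fv + rng.standard_normal((hp.k_max, N)) / np.sqrt(st.lam_x)[:, None]
    return st


def sample_y_given_state(
    state: LatentState, mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Forward draw of Y given the state (masked entries set to NaN)."""
    D, N = mask.shape
    Y = state.G @ state.X + rng.standard_normal((D, N)) / np.sqrt(state.lam_y)[:, None]
    return np.where(mask, Y, np.nan)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

_SWEEP_ORDER = ("latent", "loadings", "latent", "regression", "sparsity", "noise")


def gibbs_sweep(
    state: LatentState,
    Y: SensitivityMatrix,
    F: FeatureMatrix,
    rng: np.random.Generator,
    drug_graph: RelationGraph | None = None,
    feat_graph: RelationGraph | None = None,
) -> LatentState:
    """One full sweep over all unknowns in the fixed scan order.

    X is refreshed twice per sweep -- once before the loadings block and
    again before the regression block.  The repeated block is still a valid
    Gibbs scan (any fixed order of exact conditionals is) and markedly
    improves mixing between near-rotational modes of (G, X): the extra
    refresh lets X re-align with the just-updated loadings before the
    feature supports are resampled.
    """
    update_latent(state, Y, F, rng)
    update_loadings(state, Y, drug_graph, rng)
    update_latent(state, Y, F, rng)
    update_regression(state, F, feat_graph, rng)
    update_sparsity(state, rng)
    update_noise(state, Y, F, rng)
    return state


def _effective_graph(graph: RelationGraph | None, use: bool) -> RelationGraph | None:
    # an edgeless or all-zero-weight graph carries no coupling: treat as absent
    if graph is None or not use or graph.is_null():
        return None
    return graph


def run_gibbs(
    Y: SensitivityMatrix,
    F: FeatureMatrix,
    cfg: GibbsConfig,
    drug_graph: RelationGraph | None = None,
    feat_graph: RelationGraph | None = None,
) -> PosteriorTrace:
    """Run the full sampler and collect thinned post-burn-in snapshots.

    Inputs must already share cell-line order (use :func:`fit` for label
    alignment and standardization).  Snapshot ``i`` is recorded when
    ``i > burn_in`` and ``(i - burn_in - 1) % thin == 0``.
    """
    if list(Y.cell_ids) != list(F.cell_ids):
        raise ValueError("Y and F cell lines are not aligned")
    if not np.all(np.isfinite(F.values)):
        raise ValueError("non-finite values in feature matrix")
    drug_graph = _effective_graph(drug_graph, cfg.use_drug_mrf)
    feat_graph = _effective_graph(feat_graph, cfg.use_feature_mrf)

    D, N = Y.values.shape
    P = F.n_features
    hp = cfg.hyperparams.resolved(P)
    rng = np.random.default_rng(cfg.seed)
    state = initial_state(D, N, P, hp, F.values, rng)

    states: list[LatentState] = []
    ljs: list[float] = []
    log_every = max(1, cfg.n_iter // 10)
    warned_full = False
    for it in range(1, cfg.n_iter + 1):
        gibbs_sweep(state, Y, F, rng, drug_graph, feat_graph)
        active = state.active_lc_count()
        if active >= hp.k_max and not warned_full:
            logger.warning(
                "active LC count reached the truncation level k_max=%d; "
                "consider increasing it", hp.k_max,
            )
            warned_full = True
        if it % log_every == 0:
            logger.info("sweep %d/%d: %d active LCs", it, cfg.n_iter, active)
        if it > cfg.burn_in and (it - cfg.burn_in - 1) % cfg.thin == 0:
            states.append(state.copy())
            ljs.append(log_joint(state, Y, F, drug_graph, feat_graph))
    return PosteriorTrace(states=states, log_joint=ljs, config_echo=cfg)


def fit(
    Y: SensitivityMatrix,
    F: FeatureMatrix,
    cfg: GibbsConfig,
    drug_graph: RelationGraph | None = None,
    feat_graph: RelationGraph | None = None,
) -> PosteriorTrace:
    """Standardize, align cell lines by label, and run the sampler.

    Y rows and continuous F rows are z-scored with training statistics
    (stored on the returned trace so predictions for held-out cell lines can
    replay the transform); binary mutation rows are left untouched.
    """
    if set(Y.cell_ids) != set(F.cell_ids):
        raise ValueError("Y and F have different cell-line sets")
    order = [F.cell_ids.index(c) for c in Y.cell_ids]
    Fv = F.values[:, order]

    y_scaler = Standardizer.fit(np.where(Y.observed_mask, Y.values, np.nan))
    skip = np.array([k == "mutation" for k in F.kind_of])
    f_scaler = Standardizer.fit(Fv, skip=skip)

    Ys = SensitivityMatrix(
        values=np.where(Y.observed_mask, y_scaler.transform(np.where(Y.observed_mask, Y.values, 0.0)), np.nan),
        drug_ids=Y.drug_ids,
        cell_ids=Y.cell_ids,
        observed_mask=Y.observed_mask,
    )
    Fs = FeatureMatrix(
        values=f_scaler.transform(Fv),
        feature_ids=F.feature_ids,
        gene_of=F.gene_of,
        kind_of=F.kind_of,
        cell_ids=list(Y.cell_ids),
    )
    trace = run_gibbs(Ys, Fs, cfg, drug_graph, feat_graph)
    trace.drug_ids = list(Y.drug_ids)
    trace.cell_ids = list(Y.cell_ids)
    trace.feature_ids = list(F.feature_ids)
    trace.y_scaler = y_scaler
    trace.f_scaler = f_scaler
    return trace
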
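"""Model state, domain containers and the log joint density.

The model is a sparse discriminative (reduced-rank) factor analysis for a
drug-by-cell-line sensitivity matrix ``Y`` and a genomic-feature-by-cell-line
matrix ``F``::

    Y = G X + eps        eps_dn ~ N(0, 1/lam_y[d])
    X = B F + w          w_kn   ~ N(0, 1/lam_x[k])

Rows of ``G`` (drugs) load sparsely on K latent characteristics (LCs) through
a binary matrix ``Z`` with a finite-truncation Indian-buffet-process prior,
and each LC is predicted from a sparse subset of genomic features through a
binary matrix ``V`` with independent Bernoulli(pi_p) feature-inclusion
probabilities.  Both sets of coefficients carry spike-and-slab priors with a
unit-variance slab; noise precisions are per-drug and per-LC with hierarchical
exponential (Gamma shape-1) priors.  Optional Markov-random-field terms couple
drugs that share an inhibition target and features of the same gene.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

FEATURE_KINDS = ("expression", "cnv", "mutation")


def _check_labels(labels: Sequence[str], n: int, what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValueError(f"{what}: expected {n} labels, got {len(labels)}")
    if len(set(labels)) != len(labels):
        raise ValueError(f"{what}: duplicate labels")
    return labels


@dataclass
class SensitivityMatrix:
    """D drugs x N cell lines of continuous sensitivity scores.

    Missing entries are permitted: they are ``NaN`` in ``values`` and False in
    ``observed_mask``.  Every drug and every cell line must retain at least
    one observed entry.
    """

    values: np.ndarray
    drug_ids: list[str]
    cell_ids: list[str]
    observed_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        D, N = self.values.shape
        self.drug_ids = _check_labels(self.drug_ids, D, "drug_ids")
        self.cell_ids = _check_labels(self.cell_ids, N, "cell_ids")
        if self.observed_mask is None:
            self.observed_mask = ~np.isnan(self.values)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.observed_mask.shape != (D, N):
            raise ValueError("observed_mask shape mismatch")
        if np.isnan(self.values[self.observed_mask]).any():
            raise ValueError("NaN marked as observed")
        if not self.observed_mask.any(axis=1).all():
            raise ValueError("a drug has no observed entries")
        if not self.observed_mask.any(axis=0).all():
            raise ValueError("a cell line has no observed entries")

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureMatrix:
    """P genomic features x N cell lines.

    Each feature row is tagged with the gene it derives from and its kind
    (``expression``, ``cnv`` or ``mutation``).  Mutation rows must be binary.
    """

    values: np.ndarray
    feature_ids: list[str]
    gene_of: list[str]
    kind_of: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        P, N = self.values.shape
        self.feature_ids = _check_labels(self.feature_ids, P, "feature_ids")
        self.cell_ids = _check_labels(self.cell_ids, N, "cell_ids")
        self.gene_of = [str(g) for g in self.gene_of]
        self.kind_of = [str(k) for k in self.kind_of]
        if len(self.gene_of) != P or len(self.kind_of) != P:
            raise ValueError("gene_of/kind_of length mismatch")
        for k in self.kind_of:
            if k not in FEATURE_KINDS:
                raise ValueError(f"unknown feature kind {k!r}")
        mut = np.array([k == "mutation" for k in self.kind_of])
        if mut.any():
            vals = self.values[mut]
            if not np.isin(vals[~np.isnan(vals)], (0.0, 1.0)).all():
                raise ValueError("mutation rows must be binary")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class RelationGraph:
    """Weighted undirected graph over drugs or features.

    Used by the MRF priors: an edge (i, j, w) adds ``w * z_i * z_j`` to the
    unnormalized log prior of every binary column it touches.
    """

    n_nodes: int
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        norm = []
        for i, j, w in self.edges:
            i, j, w = int(i), int(j), float(w)
            if i == j:
                raise ValueError("self-loop in relation graph")
            if i > j:
                i, j = j, i
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError("edge index out of range")
            if (i, j) in seen:
                raise ValueError(f"duplicate edge ({i}, {j})")
            if w < 0:
                raise ValueError("negative edge weight")
            seen.add((i, j))
            norm.append((i, j, w))
        self.edges = norm

    def weight_matrix(self) -> np.ndarray:
        """Dense symmetric weight matrix (zero diagonal)."""
        W = np.zeros((self.n_nodes, self.n_nodes))
        for i, j, w in self.edges:
            W[i, j] = W[j, i] = w
        return W

    def is_null(self) -> bool:
        """True when the graph carries no coupling (no edges or all zero)."""
        return all(w == 0.0 for _, _, w in self.edges)


@dataclass
class Hyperparams:
    """Fixed hyperparameters of the priors.

    alpha
        IBP concentration; under the IBP limit the expected number of active
        LCs is alpha times the harmonic number of the drug count, so the
        default of 1 keeps the prior LC count modest (about 3.6 for 20
        drugs) while leaving the posterior free to grow.
    beta
        feature-sparsity concentration; prior inclusion rates are
        pi_p ~ Beta(beta/P, 1), so small beta/P keeps features rare.  The
        default ``None`` resolves to 0.01 * P at fit time, i.e. a prior
        inclusion rate parameter of 0.01 per feature regardless of P.
    k_max
        truncation level of the finite IBP approximation.
    mrf_weight
        default edge weight used when building relation graphs.
    """

    alpha: float = 1.0
    beta: float | None = None
    k_max: int = 50
    mrf_weight: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.mrf_weight >= 0):
            raise ValueError("alpha must be > 0 and mrf_weight >= 0")
        if self.beta is not None and not self.beta > 0:
            raise ValueError("beta must be > 0")
        if int(self.k_max) < 1:
            raise ValueError("k_max must be >= 1")
        self.k_max = int(self.k_max)

    def resolved(self, P: int) -> "Hyperparams":
        """Concrete hyperparameters for a dataset with P features."""
        beta = 0.01 * P if self.beta is None else self.beta
        return Hyperparams(alpha=self.alpha, beta=beta, k_max=self.k_max,
                           mrf_weight=self.mrf_weight)


@dataclass
class LatentState:
    """One full configuration of all model unknowns."""

    Z: np.ndarray          # D x K binary: drug d uses LC k
    G: np.ndarray          # D x K loadings, exactly 0 where Z == 0
    v: np.ndarray          # K Bernoulli rates in (0, 1)
    X: np.ndarray          # K x N latent characteristic values
    V: np.ndarray          # K x P binary: LC k uses feature p
    B: np.ndarray          # K x P coefficients, exactly 0 where V == 0
    pi: np.ndarray         # P inclusion rates in (0, 1)
    lam_y: np.ndarray      # D per-drug noise precisions
    b_y: float
    lam_x: np.ndarray      # K per-LC noise precisions
    b_x: float
    hyper: Hyperparams

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=np.int8)
        self.V = np.asarray(self.V, dtype=np.int8)
        for name in ("G", "v", "X", "B", "pi", "lam_y", "lam_x"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    @property
    def K(self) -> int:
        return self.Z.shape[1]

    @property
    def n_drugs(self) -> int:
        return self.Z.shape[0]

    @property
    def n_features(self) -> int:
        return self.V.shape[1]

    def active_lc_count(self) -> int:
        """Number of LCs used by at least one drug."""
        return int((self.Z.sum(axis=0) > 0).sum())

    def validate(self) -> None:
        D, K = self.Z.shape
        P = self.V.shape[1]
        N = self.X.shape[1]
        if self.G.shape != (D, K) or self.X.shape != (K, N):
            raise ValueError("G/X shape mismatch")
        if self.V.shape != (K, P) or self.B.shape != (K, P):
            raise ValueError("V/B shape mismatch")
        if self.v.shape != (K,) or self.pi.shape != (P,):
            raise ValueError("v/pi shape mismatch")
        if self.lam_y.shape != (D,) or self.lam_x.shape != (K,):
            raise ValueError("precision shape mismatch")
        if np.any(self.G[self.Z == 0] != 0.0):
            raise ValueError("G must be exactly 0 where Z == 0")
        if np.any(self.B[self.V == 0] != 0.0):
            raise ValueError("B must be exactly 0 where V == 0")
        if not (np.all(self.v > 0) and np.all(self.v < 1)):
            raise ValueError("v must lie in (0, 1)")
        if not (np.all(self.pi > 0) and np.all(self.pi < 1)):
            raise ValueError("pi must lie in (0, 1)")
        if not (np.all(self.lam_y > 0) and np.all(self.lam_x > 0)):
            raise ValueError("precisions must be positive")
        if not (self.b_y > 0 and self.b_x > 0):
            raise ValueError("b_y, b_x must be positive")

    def copy(self) -> "LatentState":
        return copy.deepcopy(self)


@dataclass
class GibbsConfig:
    """Sampler configuration; defaults follow the reference protocol of
    10,000 sweeps with the first half discarded and 1-in-10 thinning."""

    n_iter: int = 10_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    use_drug_mrf: bool = True
    use_feature_mrf: bool = True

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class Standardizer:
    """Per-row location/scale transform fitted on training columns only.

    Rows flagged in ``skip`` (binary mutation features) pass through
    untouched.  Constant rows get unit scale to avoid division by zero.
    """

    mean: np.ndarray
    sd: np.ndarray
    skip: np.ndarray

    @classmethod
    def fit(cls, values: np.ndarray, skip: np.ndarray | None = None) -> "Standardizer":
        P = values.shape[0]
        if skip is None:
            skip = np.zeros(P, dtype=bool)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(values, axis=1)
            sd = np.nanstd(values, axis=1, ddof=0)
        mean = np.where(skip, 0.0, mean)
        sd = np.where(skip | (sd == 0) | ~np.isfinite(sd), 1.0, sd)
        mean = np.where(np.isfinite(mean), mean, 0.0)
        return cls(mean=mean, sd=sd, skip=np.asarray(skip, bool))

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean[:, None]) / self.sd[:, None]

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return values * self.sd[:, None] + self.mean[:, None]


@dataclass
class PosteriorTrace:
    """Post-burn-in snapshots of the chain; the unit of prediction.

    Besides the snapshots, carries the fitted standardizers and label order
    so that held-out prediction can replay the training-time preprocessing.
    """

    states: list[LatentState]
    log_joint: list[float]
    config_echo: GibbsConfig
    drug_ids: list[str] | None = None
    cell_ids: list[str] | None = None
    feature_ids: list[str] | None = None
    y_scaler: Standardizer | None = None
    f_scaler: Standardizer | None = None

    def __post_init__(self) -> None:
        if len(self.states) != len(self.log_joint) or len(self.states) < 1:
            raise ValueError("states and log_joint must have equal length >= 1")

    def best_state(self) -> LatentState:
        """The snapshot with the highest log joint (interpretation summary)."""
        return self.states[int(np.argmax(self.log_joint))]


# ---------------------------------------------------------------------------
# log joint density
# ---------------------------------------------------------------------------

_LOG_2PI = float(np.log(2.0 * np.pi))


def _gauss_ll(resid: np.ndarray, prec: np.ndarray) -> float:
    # sum of N(resid | 0, 1/prec) log densities; prec broadcast over resid
    return float(0.5 * np.sum(np.log(prec) - _LOG_2PI - prec * resid**2))


def log_joint(
    state: LatentState,
    Y: SensitivityMatrix,
    F: FeatureMatrix,
    drug_graph: RelationGraph | None = None,
    feat_graph: RelationGraph | None = None,
) -> float:
    """Unnormalized log joint density of the full generative model.

    Sums the masked Gaussian likelihood of ``Y`` given ``G X``, the Gaussian
    density of ``X`` given ``B F``, all priors (spike-and-slab coefficients,
    Bernoulli supports, Beta rates, hierarchical Gamma noise), and, when
    graphs are supplied, the unnormalized MRF couplings.  The MRF partition
    function is constant for fixed graphs, so differences of this quantity
    remain valid for MCMC diagnostics.
    """
    D, N = Y.values.shape
    P = F.n_features
    if state.n_drugs != D or state.X.shape[1] != N or state.n_features != P:
        raise ValueError("state dimensions inconsistent with data")
    for arr in (state.G, state.X, state.B, state.v, state.pi, state.lam_y, state.lam_x):
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite values in state")
    hp = state.hyper
    K = state.K

    mask = Y.observed_mask
    resid_y = np.where(mask, Y.values - state.G @ state.X, 0.0)
    ll_y = _gauss_ll(resid_y[mask], np.broadcast_to(state.lam_y[:, None], (D, N))[mask])

    resid_x = state.X - state.B @ F.values
    ll_x = _gauss_ll(resid_x, state.lam_x[:, None])

    # spike-and-slab: active coefficients ~ N(0, 1); spikes contribute 0 mass
    lp = ll_y + ll_x
    lp += float(np.sum(-0.5 * (_LOG_2PI + state.G[state.Z == 1] ** 2)))
    lp += float(np.sum(-0.5 * (_LOG_2PI + state.B[state.V == 1] ** 2)))

    # supports given rates
    lp += float(np.sum(state.Z * np.log(state.v) + (1 - state.Z) * np.log1p(-state.v)))
    lp += float(np.sum(state.V * np.log(state.pi[None, :]) + (1 - state.V) * np.log1p(-state.pi[None, :])))

    # Beta(a, 1) rates: log a + (a - 1) log v
    a_v = hp.alpha / hp.k_max
    lp += float(K * np.log(a_v) + (a_v - 1.0) * np.sum(np.log(state.v)))
    a_pi = hp.beta / P
    lp += float(P * np.log(a_pi) + (a_pi - 1.0) * np.sum(np.log(state.pi)))

    # hierarchical noise: lam | b ~ Exponential(rate b), b ~ Exponential(1)
    lp += float(D * np.log(state.b_y) - state.b_y * np.sum(state.lam_y)) - state.b_y
    lp += float(K * np.log(state.b_x) - state.b_x * np.sum(state.lam_x)) - state.b_x

    if drug_graph is not None:
        if drug_graph.n_nodes != D:
            raise ValueError("drug graph size mismatch")
        for i, j, w in drug_graph.edges:
            lp += w * float(state.Z[i] @ state.Z[j])
    if feat_graph is not None:
        if feat_graph.n_nodes != P:
            raise ValueError("feature graph size mismatch")
        for i, j, w in feat_graph.edges:
            lp += w * float(state.V[:, i] @ state.V[:, j])
    return lp


def predict_mean(trace: PosteriorTrace, F_new: FeatureMatrix) -> np.ndarray:
    """Posterior-mean prediction ``E[G B] F_new`` for new cell lines.

    Features are aligned by id with the training feature set; the training
    standardizers (when the trace carries them) are applied to ``F_new`` and
    inverted on the predictions, so output is on the original Y scale.
    Returns a D x M matrix (drugs by new cell lines).
    """
    if trace.feature_ids is not None:
        if list(F_new.feature_ids) != list(trace.feature_ids):
            raise ValueError("feature ids do not match the training features")
    Fv = F_new.values
    if trace.f_scaler is not None:
        Fv = trace.f_scaler.transform(Fv)
    GB = np.mean([s.G @ s.B for s in trace.states], axis=0)
    pred = GB @ Fv
    if trace.y_scaler is not None:
        pred = trace.y_scaler.inverse(pred)
    return pred
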
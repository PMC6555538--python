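"""Synthetic datasets drawn from the model's own generative process.

Emulates a drug-sensitivity screen: a panel of cell lines profiled for
genomic features (expression-like continuous rows plus rare binary
mutation-like rows), a handful of true latent characteristics each driven by
a few features and loading on a few drugs, and relation graphs derived from
the ground truth (drugs sharing an LC ~ drugs sharing an inhibition target;
features grouped into synthetic genes of size 1-3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .model import (
    FeatureMatrix,
    Hyperparams,
    LatentState,
    RelationGraph,
    SensitivityMatrix,
)


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults give a modest screen (20 drugs x 300 cell lines x 40 features,
    3 true LCs) at high signal-to-noise (both noise precisions 25, i.e.
    noise sd 0.2 against unit-scale signal).
    """

    D: int = 20
    N: int = 300
    P: int = 40
    K_true: int = 3
    z_density: float = 0.25
    v_density: float = 0.10
    features_per_lc: int = 4
    drugs_per_lc: int = 5
    noise_prec_y: float = 25.0
    noise_prec_x: float = 25.0
    frac_binary_features: float = 0.25
    binary_quantile: float = 0.90
    use_fixed_supports: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.K_true <= min(self.D, self.P):
            raise ValueError("K_true must be <= min(D, P)")
        if self.drugs_per_lc > self.D or self.features_per_lc > self.P:
            raise ValueError("per-LC support sizes exceed dimensions")
        if not (0 < self.z_density <= 1 and 0 < self.v_density <= 1):
            raise ValueError("densities must lie in (0, 1]")
        if not 0 <= self.frac_binary_features <= 1:
            raise ValueError("frac_binary_features must lie in [0, 1]")
        if not (self.noise_prec_y > 0 and self.noise_prec_x > 0):
            raise ValueError("noise precisions must be positive")


def _rate(count: int, total: int) -> float:
    # smoothed occupancy in (0, 1) for bookkeeping rates in the truth state
    return (count + 0.5) / (total + 1.0)


def generate(
    sc: SimConfig,
) -> tuple[SensitivityMatrix, FeatureMatrix, LatentState, RelationGraph, RelationGraph]:
    """Draw (Y, F, truth, drug_graph, feat_graph) from the generative model.

    F rows are i.i.d. standard normal; a fraction of rows is thresholded at
    the ``binary_quantile`` to produce rare binary mutation-like features.
    Supports are either fixed-size without replacement (default, giving
    identifiable ground truth) or Bernoulli at ``z_density``/``v_density``.
    """
    rng = np.random.default_rng(sc.seed)
    D, N, P, K = sc.D, sc.N, sc.P, sc.K_true

    F_raw = rng.standard_normal((P, N))
    n_bin = int(round(sc.frac_binary_features * P))
    bin_rows = rng.choice(P, size=n_bin, replace=False) if n_bin else np.array([], int)
    kinds = ["expression"] * P
    Fv = F_raw.copy()
    for p in bin_rows:
        thr = np.quantile(F_raw[p], sc.binary_quantile)
        Fv[p] = (F_raw[p] > thr).astype(float)
        kinds[p] = "mutation"

    # synthetic genes of size 1-3
    gene_of: list[str] = [""] * P
    perm = rng.permutation(P)
    g = 0
    i = 0
    while i < P:
        size = int(rng.integers(1, 4))
        for p in perm[i : i + size]:
            gene_of[p] = f"gene{g:03d}"
        g += 1
        i += size

    Z = np.zeros((D, K), dtype=np.int8)
    V = np.zeros((K, P), dtype=np.int8)
    if sc.use_fixed_supports:
        for k in range(K):
            Z[rng.choice(D, size=sc.drugs_per_lc, replace=False), k] = 1
            V[k, rng.choice(P, size=sc.features_per_lc, replace=False)] = 1
    else:
        while True:  # reject degenerate draws: every LC needs a drug and a feature
            Z = (rng.random((D, K)) < sc.z_density).astype(np.int8)
            V = (rng.random((K, P)) < sc.v_density).astype(np.int8)
            if Z.sum(axis=0).min() > 0 and V.sum(axis=1).min() > 0:
                break

    G = np.where(Z == 1, rng.standard_normal((D, K)), 0.0)
    B = np.where(V == 1, rng.standard_normal((K, P)), 0.0)
    X = B @ Fv + rng.standard_normal((K, N)) / np.sqrt(sc.noise_prec_x)
    Yv = G @ X + rng.standard_normal((D, N)) / np.sqrt(sc.noise_prec_y)

    drug_ids = [f"drug{d:03d}" for d in range(D)]
    cell_ids = [f"cell{n:04d}" for n in range(N)]
    feat_ids = [f"feat{p:03d}" for p in range(P)]

    Y = SensitivityMatrix(values=Yv, drug_ids=drug_ids, cell_ids=cell_ids)
    F = FeatureMatrix(
        values=Fv, feature_ids=feat_ids, gene_of=gene_of, kind_of=kinds, cell_ids=cell_ids
    )
    hp = Hyperparams(k_max=K).resolved(P)
    truth = LatentState(
        Z=Z,
        G=G,
        v=np.array([_rate(int(Z[:, k].sum()), D) for k in range(K)]),
        X=X,
        V=V,
        B=B,
        pi=np.array([_rate(int(V[:, p].sum()), K) for p in range(P)]),
        lam_y=np.full(D, sc.noise_prec_y),
        b_y=1.0,
        lam_x=np.full(K, sc.noise_prec_x),
        b_x=1.0,
        hyper=hp,
    )

    # drugs sharing a true LC ~ drugs sharing an inhibition target
    targets = {drug_ids[d]: {f"LC{k}" for k in range(K) if Z[d, k]} for d in range(D)}
    drug_graph = build_target_graph(targets, hp.mrf_weight, node_order=drug_ids)
    feat_graph = build_gene_graph(
        dict(zip(feat_ids, gene_of)), hp.mrf_weight, node_order=feat_ids
    )
    return Y, F, truth, drug_graph, feat_graph


def build_target_graph(
    drug_targets: Mapping[str, set],
    weight: float = 1.0,
    node_order: list[str] | None = None,
) -> RelationGraph:
    """Graph with an edge between every drug pair sharing >= 1 target."""
    if weight < 0:
        raise ValueError("weight must be >= 0")
    nodes = node_order if node_order is not None else sorted(drug_targets)
    idx = {d: i for i, d in enumerate(nodes)}
    edges = []
    for a in nodes:
        for b in nodes:
            if idx[a] < idx[b] and set(drug_targets.get(a, ())) & set(
                drug_targets.get(b, ())
            ):
                edges.append((idx[a], idx[b], weight))
    return RelationGraph(n_nodes=len(nodes), edges=edges)


def build_gene_graph(
    feature_genes: Mapping[str, str],
    weight: float = 1.0,
    node_order: list[str] | None = None,
) -> RelationGraph:
    """Graph linking all feature pairs annotated to the same gene."""
    if weight < 0:
        raise ValueError("weight must be >= 0")
    nodes = node_order if node_order is not None else sorted(feature_genes)
    idx = {f: i for i, f in enumerate(nodes)}
    by_gene: dict[str, list[str]] = {}
    for f in nodes:
        by_gene.setdefault(feature_genes[f], []).append(f)
    edges = []
    for members in by_gene.values():
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                ia, ib = idx[a], idx[b]
                edges.append((min(ia, ib), max(ia, ib), weight))
    return RelationGraph(n_nodes=len(nodes), edges=edges)
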
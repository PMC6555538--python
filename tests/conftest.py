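import numpy as np
import pytest

from dsfa.model import (
    FeatureMatrix,
    Hyperparams,
    LatentState,
    SensitivityMatrix,
)


def make_sensitivity(values, mask=None):
    values = np.asarray(values, float)
    D, N = values.shape
    return SensitivityMatrix(
        values=values,
        drug_ids=[f"d{i}" for i in range(D)],
        cell_ids=[f"c{i}" for i in range(N)],
        observed_mask=mask,
    )


def make_features(values, kinds=None, genes=None):
    values = np.asarray(values, float)
    P, N = values.shape
    return FeatureMatrix(
        values=values,
        feature_ids=[f"f{i}" for i in range(P)],
        gene_of=genes if genes is not None else [f"g{i}" for i in range(P)],
        kind_of=kinds if kinds is not None else ["expression"] * P,
        cell_ids=[f"c{i}" for i in range(N)],
    )


def make_state(Z, G, X, V, B, v=None, pi=None, lam_y=None, lam_x=None,
               b_y=1.0, b_x=1.0, hp=None):
    Z = np.atleast_2d(np.asarray(Z, np.int8))
    V = np.atleast_2d(np.asarray(V, np.int8))
    D, K = Z.shape
    P = V.shape[1]
    if hp is None:
        hp = Hyperparams(alpha=1.0, beta=float(P), k_max=K)
    return LatentState(
        Z=Z,
        G=np.atleast_2d(G),
        v=np.full(K, 0.5) if v is None else np.asarray(v, float),
        X=np.atleast_2d(X),
        V=V,
        B=np.atleast_2d(B),
        pi=np.full(P, 0.5) if pi is None else np.asarray(pi, float),
        lam_y=np.ones(D) if lam_y is None else np.asarray(lam_y, float),
        b_y=b_y,
        lam_x=np.ones(K) if lam_x is None else np.asarray(lam_x, float),
        b_x=b_x,
        hyper=hp,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_bundle():
    """A small simulated screen shared by tests that just need valid data."""
    from dsfa.simulate import SimConfig, generate

    sc = SimConfig(D=8, N=80, P=12, K_true=2, drugs_per_lc=3, features_per_lc=3, seed=11)
    return generate(sc)
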
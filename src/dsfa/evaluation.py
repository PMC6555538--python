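"""Prediction metrics, the cell-line-holdout cross-validation protocol, and
latent-characteristic interpretation tables."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .gibbs import fit
from .model import (
    FeatureMatrix,
    GibbsConfig,
    LatentState,
    PosteriorTrace,
    RelationGraph,
    SensitivityMatrix,
    predict_mean,
)


@dataclass
class FoldResult:
    fold_id: int
    held_out_cell_ids: list[str]
    pve: float
    mean_cindex: float
    per_drug_cindex: np.ndarray


@dataclass
class AssociationRow:
    lc_id: int
    drug_id: str
    feature_id: str
    rho: float
    p: float


def pve(
    y_obs: np.ndarray,
    mask: np.ndarray,
    y_pred: np.ndarray,
    train_row_means: np.ndarray,
) -> float:
    """Proportion of held-out variance explained, pooled over observed
    entries: 1 - SS_res / SS_tot with the per-drug training mean as the null
    prediction.  May be negative when predictions underperform the null."""
    mask = np.asarray(mask, bool)
    if mask.sum() < 2:
        raise ValueError("need at least 2 observed entries")
    resid = np.where(mask, y_obs - y_pred, 0.0)
    null = np.where(mask, y_obs - np.asarray(train_row_means)[:, None], 0.0)
    ss_tot = float(np.sum(null**2))
    if ss_tot == 0.0:
        raise ValueError("observations equal the training means everywhere")
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def concordance_index(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Probability that a random pair of cell lines is ordered the same way
    by prediction and observation; prediction ties score 1/2, observation
    ties are excluded from the pair count."""
    y_obs = np.asarray(y_obs, float)
    y_pred = np.asarray(y_pred, float)
    if y_obs.size < 2:
        raise ValueError("need at least 2 observations")
    do = y_obs[:, None] - y_obs[None, :]
    dp = y_pred[:, None] - y_pred[None, :]
    iu = np.triu_indices(y_obs.size, k=1)
    do, dp = do[iu], dp[iu]
    usable = do != 0
    if not usable.any():
        raise ValueError("all observations tied")
    score = np.where(dp[usable] == 0, 0.5, (np.sign(do[usable]) == np.sign(dp[usable])).astype(float))
    return float(score.mean())


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero rank variance")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _fold_assignments(N: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(N)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]


def _subset_Y(Y: SensitivityMatrix, cols: np.ndarray) -> SensitivityMatrix:
    return SensitivityMatrix(
        values=Y.values[:, cols],
        drug_ids=Y.drug_ids,
        cell_ids=[Y.cell_ids[i] for i in cols],
        observed_mask=Y.observed_mask[:, cols],
    )


def _subset_F(F: FeatureMatrix, cols: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        values=F.values[:, cols],
        feature_ids=F.feature_ids,
        gene_of=F.gene_of,
        kind_of=F.kind_of,
        cell_ids=[F.cell_ids[i] for i in cols],
    )


def cross_validate(
    Y: SensitivityMatrix,
    F: FeatureMatrix,
    cfg: GibbsConfig,
    n_folds: int = 10,
    drug_graph: RelationGraph | None = None,
    feat_graph: RelationGraph | None = None,
    rng: np.random.Generator | None = None,
) -> list[FoldResult]:
    """Hold out each fold of cell lines in turn, train on the remainder and
    score held-out predictions.

    Standardization statistics are computed inside :func:`fit` on training
    columns only, so no held-out information leaks into preprocessing.  Each
    fold's sampler is seeded from ``cfg.seed`` plus the fold id.
    """
    N = Y.n_cells
    if N < n_folds:
        raise ValueError("need at least n_folds cell lines")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    folds = _fold_assignments(N, n_folds, rng)
    results = []
    for fold_id, test_cols in enumerate(folds):
        train_cols = np.setdiff1d(np.arange(N), test_cols)
        Y_tr, F_tr = _subset_Y(Y, train_cols), _subset_F(F, train_cols)
        Y_te, F_te = _subset_Y(Y, test_cols), _subset_F(F, test_cols)
        fold_cfg = replace(cfg, seed=cfg.seed + fold_id)
        trace = fit(Y_tr, F_tr, fold_cfg, drug_graph, feat_graph)
        pred = predict_mean(trace, F_te)
        with np.errstate(invalid="ignore"):
            train_means = np.nanmean(np.where(Y_tr.observed_mask, Y_tr.values, np.nan), axis=1)
        fold_pve = pve(np.where(Y_te.observed_mask, Y_te.values, 0.0), Y_te.observed_mask, pred, train_means)
        per_drug = np.full(Y.n_drugs, np.nan)
        for d in range(Y.n_drugs):
            m = Y_te.observed_mask[d]
            obs = Y_te.values[d, m]
            if m.sum() >= 2 and np.unique(obs).size >= 2:
                per_drug[d] = concordance_index(obs, pred[d, m])
        results.append(
            FoldResult(
                fold_id=fold_id,
                held_out_cell_ids=list(Y_te.cell_ids),
                pve=fold_pve,
                mean_cindex=float(np.nanmean(per_drug)),
                per_drug_cindex=per_drug,
            )
        )
    return results


def lc_association_table(
    trace: PosteriorTrace,
    Y: SensitivityMatrix,
    F: FeatureMatrix,
    bh_adjust: bool = False,
) -> list[AssociationRow]:
    """Per-LC drug-feature Spearman associations from the best snapshot.

    The trace is summarized by its maximum-log-joint state (per-snapshot LC
    labels are not aligned across sweeps, so averaging supports is not
    meaningful); for every active LC k, each (drug with Z_dk=1, feature with
    V_kp=1) pair is tested by rank correlation over the cell lines observed
    for that drug.  Pairs with degenerate ranks are skipped.
    """
    state = trace.best_state()
    rows: list[AssociationRow] = []
    for k in range(state.K):
        drugs = np.flatnonzero(state.Z[:, k])
        feats = np.flatnonzero(state.V[k])
        if drugs.size == 0:
            continue
        for d in drugs:
            m = Y.observed_mask[d]
            for p in feats:
                x, y = Y.values[d, m], F.values[p, m]
                if m.sum() < 3 or np.unique(x).size < 2 or np.unique(y).size < 2:
                    continue
                rho, pval = spearman(x, y)
                rows.append(
                    AssociationRow(
                        lc_id=k,
                        drug_id=Y.drug_ids[d],
                        feature_id=F.feature_ids[p],
                        rho=rho,
                        p=pval,
                    )
                )
    if bh_adjust and rows:
        pvals = np.array([r.p for r in rows])
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, pvals[i] * m / (rank_idx + 1))
            adj[i] = running
        for r, q in zip(rows, adj):
            r.p = float(q)
    return rows


def associations_to_frame(rows: list[AssociationRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.lc_id, r.drug_id, r.feature_id, r.rho, r.p) for r in rows],
        columns=["lc_id", "drug_id", "feature_id", "rho", "p"],
    )


def folds_to_frame(results: list[FoldResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.fold_id, ";".join(r.held_out_cell_ids), r.pve, r.mean_cindex)
            for r in results
        ],
        columns=["fold_id", "held_out_cell_ids", "pve", "mean_cindex"],
    )


# ---------------------------------------------------------------------------
# recovery scoring against a known truth
# ---------------------------------------------------------------------------

def active_lc_mode(trace: PosteriorTrace) -> int:
    """Most frequent active-LC count across the trace (ties -> smallest)."""
    counts = np.array([s.active_lc_count() for s in trace.states])
    vals, freq = np.unique(counts, return_counts=True)
    return int(vals[np.argmax(freq)])


def z_support_f1(Z_est: np.ndarray, Z_true: np.ndarray) -> float:
    """Pooled F1 of the estimated Z support after greedy LC matching.

    True columns are greedily matched (best-F1-first, without replacement)
    to active estimated columns; entries of unmatched columns on either side
    count as misses/false alarms.
    """
    Z_est = np.asarray(Z_est) > 0
    Z_true = np.asarray(Z_true) > 0
    active = [k for k in range(Z_est.shape[1]) if Z_est[:, k].any()]
    pairs = []
    for kt in range(Z_true.shape[1]):
        for ke in active:
            tp = int((Z_true[:, kt] & Z_est[:, ke]).sum())
            fp = int((~Z_true[:, kt] & Z_est[:, ke]).sum())
            fn = int((Z_true[:, kt] & ~Z_est[:, ke]).sum())
            f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
            pairs.append((f1, kt, ke))
    pairs.sort(key=lambda t: -t[0])
    used_t: set[int] = set()
    used_e: set[int] = set()
    tp = fp = fn = 0
    for f1, kt, ke in pairs:
        if kt in used_t or ke in used_e:
            continue
        used_t.add(kt)
        used_e.add(ke)
        tp += int((Z_true[:, kt] & Z_est[:, ke]).sum())
        fp += int((~Z_true[:, kt] & Z_est[:, ke]).sum())
        fn += int((Z_true[:, kt] & ~Z_est[:, ke]).sum())
    for kt in range(Z_true.shape[1]):
        if kt not in used_t:
            fn += int(Z_true[:, kt].sum())
    for ke in active:
        if ke not in used_e:
            fp += int(Z_est[:, ke].sum())
    if tp == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)
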
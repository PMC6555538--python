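"""File formats: labeled matrices, annotation tables, dose-response
summaries and trace serialization.

Matrices are TSV/CSV with the first row holding cell-line (column) labels and
the first column holding row labels; empty cells are missing values.  The
delimiter is inferred from the file extension (``.csv`` -> comma, anything
else -> tab).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    FeatureMatrix,
    GibbsConfig,
    Hyperparams,
    LatentState,
    PosteriorTrace,
    RelationGraph,
    SensitivityMatrix,
    Standardizer,
)


def _delim(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labeled matrix; duplicate labels raise, empty cells are NaN."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delim(path), index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate row labels")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate column labels")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_delim(path), na_rep="")


def sensitivity_to_frame(Y: SensitivityMatrix) -> pd.DataFrame:
    return pd.DataFrame(
        np.where(Y.observed_mask, Y.values, np.nan),
        index=Y.drug_ids,
        columns=Y.cell_ids,
    )


def frame_to_sensitivity(df: pd.DataFrame) -> SensitivityMatrix:
    return SensitivityMatrix(
        values=df.to_numpy(float),
        drug_ids=list(df.index),
        cell_ids=list(df.columns),
    )


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (item, label) -> mapping item -> set of labels."""
    df = pd.read_csv(Path(path), sep="\t", header=None, names=["item", "label"], dtype=str)
    out: dict[str, set[str]] = {}
    for item, label in zip(df["item"], df["label"]):
        out.setdefault(item, set()).add(label)
    return out


# ---------------------------------------------------------------------------
# dose-response summarization
# ---------------------------------------------------------------------------

def active_area(doses: np.ndarray, viability: np.ndarray) -> float:
    """Integrated area above the dose-response curve on a log10 dose axis.

    ``viability`` is fraction-of-control; inhibition 1 - viability is
    clipped at 0 so super-viability never yields negative area.  Units are
    inhibition x dose-decades.  This is the generic well-defined alternative
    to IC50 (which does not exist when 50% inhibition is never reached).
    """
    doses = np.asarray(doses, float)
    viability = np.asarray(viability, float)
    if doses.size < 2:
        raise ValueError("need at least 2 dose points")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be strictly increasing")
    inhibition = np.clip(1.0 - viability, 0.0, None)
    return float(np.trapezoid(inhibition, np.log10(doses)))


def active_area_table(long_df: pd.DataFrame) -> pd.DataFrame:
    """Summarize a long dose-response table into a drug x cell matrix.

    Expects columns ``drug``, ``cell``, ``dose``, ``viability``; each
    (drug, cell) group is sorted by dose and reduced to its active area.
    """
    required = {"drug", "cell", "dose", "viability"}
    missing = required - set(long_df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    records = []
    for (drug, cell), grp in long_df.groupby(["drug", "cell"], sort=True):
        grp = grp.sort_values("dose")
        records.append(
            (drug, cell, active_area(grp["dose"].to_numpy(), grp["viability"].to_numpy()))
        )
    out = pd.DataFrame(records, columns=["drug", "cell", "actarea"])
    return out.pivot(index="drug", columns="cell", values="actarea")


# ---------------------------------------------------------------------------
# trace serialization: per-snapshot flat files + JSON manifest
# ---------------------------------------------------------------------------

_FMT = "%.17g"


def _save_arr(path: Path, arr: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(arr), fmt=_FMT, delimiter="\t")


def _load_arr(path: Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def save_trace(trace: PosteriorTrace, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = trace.config_echo
    manifest = {
        "n_states": len(trace.states),
        "log_joint": trace.log_joint,
        "config": {
            "n_iter": cfg.n_iter,
            "burn_in": cfg.burn_in,
            "thin": cfg.thin,
            "seed": cfg.seed,
            "use_drug_mrf": cfg.use_drug_mrf,
            "use_feature_mrf": cfg.use_feature_mrf,
            "hyperparams": dataclasses.asdict(cfg.hyperparams),
        },
        "drug_ids": trace.drug_ids,
        "cell_ids": trace.cell_ids,
        "feature_ids": trace.feature_ids,
        "y_scaler": _scaler_dict(trace.y_scaler),
        "f_scaler": _scaler_dict(trace.f_scaler),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for i, st in enumerate(trace.states):
        sd = outdir / f"state_{i:05d}"
        sd.mkdir(exist_ok=True)
        for name in ("Z", "G", "X", "V", "B"):
            _save_arr(sd / f"{name}.tsv", getattr(st, name))
        scalars = {
            "v": st.v.tolist(),
            "pi": st.pi.tolist(),
            "lam_y": st.lam_y.tolist(),
            "lam_x": st.lam_x.tolist(),
            "b_y": st.b_y,
            "b_x": st.b_x,
        }
        (sd / "scalars.json").write_text(json.dumps(scalars))


def _scaler_dict(s: Standardizer | None) -> dict | None:
    if s is None:
        return None
    return {"mean": s.mean.tolist(), "sd": s.sd.tolist(), "skip": s.skip.tolist()}


def _scaler_from(d: dict | None) -> Standardizer | None:
    if d is None:
        return None
    return Standardizer(
        mean=np.array(d["mean"]), sd=np.array(d["sd"]), skip=np.array(d["skip"], bool)
    )


def load_trace(outdir: str | Path) -> PosteriorTrace:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    c = manifest["config"]
    cfg = GibbsConfig(
        n_iter=c["n_iter"],
        burn_in=c["burn_in"],
        thin=c["thin"],
        seed=c["seed"],
        hyperparams=Hyperparams(**c["hyperparams"]),
        use_drug_mrf=c["use_drug_mrf"],
        use_feature_mrf=c["use_feature_mrf"],
    )
    hp = cfg.hyperparams
    states = []
    for i in range(manifest["n_states"]):
        sd = outdir / f"state_{i:05d}"
        arrs = {name: _load_arr(sd / f"{name}.tsv") for name in ("Z", "G", "X", "V", "B")}
        sc = json.loads((sd / "scalars.json").read_text())
        states.append(
            LatentState(
                Z=arrs["Z"].astype(np.int8),
                G=arrs["G"],
                v=np.array(sc["v"]),
                X=arrs["X"],
                V=arrs["V"].astype(np.int8),
                B=arrs["B"],
                pi=np.array(sc["pi"]),
                lam_y=np.array(sc["lam_y"]),
                b_y=sc["b_y"],
                lam_x=np.array(sc["lam_x"]),
                b_x=sc["b_x"],
                hyper=hp,
            )
        )
    return PosteriorTrace(
        states=states,
        log_joint=list(manifest["log_joint"]),
        config_echo=cfg,
        drug_ids=manifest["drug_ids"],
        cell_ids=manifest["cell_ids"],
        feature_ids=manifest["feature_ids"],
        y_scaler=_scaler_from(manifest["y_scaler"]),
        f_scaler=_scaler_from(manifest["f_scaler"]),
    )


# ---------------------------------------------------------------------------
# simulation bundle
# ---------------------------------------------------------------------------

def save_bundle(
    outdir: str | Path,
    Y: SensitivityMatrix,
    F: FeatureMatrix,
    truth: LatentState | None,
    drug_graph: RelationGraph | None,
    feat_graph: RelationGraph | None,
    config_echo: dict | None = None,
) -> None:
    """Write a full dataset (Y, F, annotations, truth, graphs) as flat files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(sensitivity_to_frame(Y), outdir / "Y.tsv")
    write_matrix(
        pd.DataFrame(F.values, index=F.feature_ids, columns=F.cell_ids),
        outdir / "F.tsv",
    )
    pd.DataFrame(
        {"feature": F.feature_ids, "gene": F.gene_of, "kind": F.kind_of}
    ).to_csv(outdir / "features.tsv", sep="\t", index=False)
    meta: dict = {"config": config_echo}
    if drug_graph is not None:
        meta["drug_graph"] = {"n_nodes": drug_graph.n_nodes, "edges": drug_graph.edges}
    if feat_graph is not None:
        meta["feat_graph"] = {"n_nodes": feat_graph.n_nodes, "edges": feat_graph.edges}
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))
    if truth is not None:
        td = outdir / "truth"
        td.mkdir(exist_ok=True)
        for name in ("Z", "G", "X", "V", "B"):
            _save_arr(td / f"{name}.tsv", getattr(truth, name))


def load_feature_matrix(matrix_path: str | Path, annot_path: str | Path) -> FeatureMatrix:
    """Assemble a FeatureMatrix from a values matrix and a feature annotation
    table with columns ``feature``, ``gene``, ``kind``."""
    df = read_matrix(matrix_path)
    ann = pd.read_csv(Path(annot_path), sep="\t", dtype=str).set_index("feature")
    ann = ann.reindex(df.index)
    if ann["gene"].isna().any():
        raise ValueError("annotation missing for some features")
    return FeatureMatrix(
        values=df.to_numpy(float),
        feature_ids=list(df.index),
        gene_of=list(ann["gene"]),
        kind_of=list(ann["kind"]),
        cell_ids=list(df.columns),
    )


def graph_from_meta(meta: dict, key: str) -> RelationGraph | None:
    g = meta.get(key)
    if g is None:
        return None
    return RelationGraph(n_nodes=g["n_nodes"], edges=[tuple(e) for e in g["edges"]])
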
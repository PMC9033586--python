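"""Plain-text dataset I/O.

Count matrices travel as an MTX triplet in the CellRanger dialect
(``matrix.mtx`` with 1-based coordinates, genes as rows; ``barcodes.tsv``;
``features.tsv`` with id, name and feature type), cell metadata and ground
truth as TSV, ligand–receptor tables and survival cohorts as CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from lnstroma.qc import QCReport
from lnstroma.simulate import (
    CloneSpec,
    EffectSpec,
    GroundTruth,
    InteractionSpec,
    SurvivalEffect,
)


def write_mtx_dir(adata: AnnData, outdir) -> Path:
    """Write counts as matrix.mtx + barcodes.tsv + features.tsv (+ metadata.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo(), field="integer")
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", index=False, header=False)
    feats = pd.DataFrame(
        {"id": adata.var_names, "name": adata.var_names, "type": "Gene Expression"}
    )
    feats.to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    adata.obs.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    return outdir


def read_mtx_dir(indir) -> AnnData:
    indir = Path(indir)
    X = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx").T)
    barcodes = pd.read_csv(indir / "barcodes.tsv", header=None)[0].astype(str)
    feats = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    obs = pd.DataFrame(index=barcodes.to_numpy())
    meta_path = indir / "metadata.tsv"
    if meta_path.exists():
        obs = pd.read_csv(meta_path, sep="\t")
        obs.index = obs["cell_id"].astype(str).to_numpy()
    return AnnData(X=X, obs=obs, var=pd.DataFrame(index=feats[0].astype(str).to_numpy()))


def write_ground_truth(truth: GroundTruth, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frame in truth.frames().items():
        frame.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    return outdir


_TRUTH_TYPES = {
    "planted_deg": EffectSpec,
    "planted_clones": CloneSpec,
    "planted_interactions": InteractionSpec,
    "survival_effects": SurvivalEffect,
}


def read_ground_truth(indir) -> GroundTruth:
    indir = Path(indir)
    kwargs = {}
    for name, cls in _TRUTH_TYPES.items():
        path = indir / f"{name}.tsv"
        items = []
        if path.exists():
            try:
                frame = pd.read_csv(path, sep="\t")
            except pd.errors.EmptyDataError:
                frame = pd.DataFrame()
            items = [cls(**row) for row in frame.to_dict("records")]
        kwargs[name] = items
    return GroundTruth(**kwargs)


def write_qc_report(report: QCReport, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(report), indent=2))


def write_lr_table(table: pd.DataFrame, path) -> None:
    table[["ligand", "receptor"]].to_csv(path, index=False)


def read_lr_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if list(table.columns[:2]) != ["ligand", "receptor"]:
        raise ValueError("ligand-receptor table must have header 'ligand,receptor'")
    if table.duplicated(["ligand", "receptor"]).any():
        raise ValueError("duplicate ligand-receptor pairs")
    return table


def write_survival_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_survival_cohort(path, time_unit: str = "years") -> pd.DataFrame:
    cohort = pd.read_csv(path)
    if time_unit == "months":
        cohort["time"] = cohort["time"] / 12.0
    elif time_unit != "years":
        raise ValueError("time_unit must be 'years' or 'months'")
    return cohort
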
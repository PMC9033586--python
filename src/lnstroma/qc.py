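"""Cell/gene quality control and normalization.

The filtering order is fixed: lowly detected genes first, then low-complexity
cells, then the median-derived doublet and mitochondrial rules, then
normalization.  Expression thresholds used downstream (light-chain calling,
min-pct filters) are defined on the log1p CP10K scale produced here.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from anndata import AnnData

from lnstroma._utils import gene_vector

RIBOSOMAL_RE = re.compile(r"^(RPL|RPS)")


@dataclass
class QCReport:
    """What a QC step removed, and the thresholds it actually applied."""

    n_genes_removed: int = 0
    n_cells_low_count: int = 0
    n_cells_doublet: int = 0
    n_cells_mito: int = 0
    thresholds: dict = field(default_factory=dict)
    empty_output: bool = False
    notes: list = field(default_factory=list)


def _detected(X) -> tuple[np.ndarray, np.ndarray]:
    """(genes detected per cell, cells detecting each gene)."""
    B = X > 0
    if sp.issparse(B):
        return np.asarray(B.sum(axis=1)).ravel(), np.asarray(B.sum(axis=0)).ravel()
    return B.sum(axis=1), B.sum(axis=0)


def filter_ribosomal(adata: AnnData) -> AnnData:
    """Drop ribosomal protein genes (^RPL/^RPS). Optional, off the main path."""
    keep = [g for g in adata.var_names if not RIBOSOMAL_RE.match(g)]
    return adata[:, keep].copy()


def filter_genes_cells(
    adata: AnnData, min_cells: int = 3, min_genes: int = 200
) -> tuple[AnnData, QCReport]:
    """Remove genes detected in fewer than ``min_cells`` cells, then cells
    expressing fewer than ``min_genes`` genes (strict "fewer than" on both).
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty input matrix")
    report = QCReport(thresholds={"min_cells": min_cells, "min_genes": min_genes})

    _, cells_per_gene = _detected(adata.X)
    gene_keep = cells_per_gene >= min_cells
    report.n_genes_removed = int((~gene_keep).sum())
    out = adata[:, gene_keep].copy()

    if out.n_vars == 0:
        report.empty_output = True
        report.notes.append("all genes removed by the min-cells rule")
        return out, report

    genes_per_cell, _ = _detected(out.X)
    cell_keep = genes_per_cell >= min_genes
    report.n_cells_low_count = int((~cell_keep).sum())
    out = out[cell_keep].copy()
    if out.n_obs == 0:
        report.empty_output = True
        report.notes.append("all cells removed by the min-genes rule")
    return out, report


def doublet_mito_filter(
    adata: AnnData,
    *,
    mito_mode: str = "fraction",
    feature_multiplier: float = 3.0,
    mito_multiplier: float = 2.0,
    mito_prefix: str = "MT-",
) -> tuple[AnnData, QCReport]:
    """Median-derived doublet and mitochondrial filters.

    Removes cells whose detected-gene count exceeds ``feature_multiplier`` x
    the median detected-gene count (possible doublets) and/or whose
    mitochondrial load exceeds ``mito_multiplier`` x the median load (possible
    apoptotic/lysed cells).  Both medians are computed on the input to this
    step; ties at the threshold are retained (strict inequality).

    Mitochondrial load is, per ``mito_mode``: ``"fraction"`` — the per-cell
    mitochondrial UMI fraction (``obs['mito_fraction']`` if present, else
    computed from genes named ``mito_prefix*``); ``"ngenes"`` — the count of
    distinct detected mitochondrial genes.
    """
    if adata.n_obs == 0:
        raise ValueError("empty input matrix")
    genes_per_cell, _ = _detected(adata.X)
    med_feat = float(np.median(genes_per_cell))
    doublet = genes_per_cell > feature_multiplier * med_feat

    mito_genes = [g for g in adata.var_names if g.startswith(mito_prefix)]
    if mito_mode == "fraction":
        if "mito_fraction" in adata.obs:
            mito_load = adata.obs["mito_fraction"].to_numpy(dtype=float)
        elif mito_genes:
            tot = np.asarray(adata.X.sum(axis=1)).ravel().astype(float)
            mt = np.asarray(adata[:, mito_genes].X.sum(axis=1)).ravel().astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                mito_load = np.where(tot > 0, mt / np.maximum(tot, 1), 0.0)
        else:
            raise ValueError("no mito_fraction column and no mitochondrial genes found")
    elif mito_mode == "ngenes":
        if not mito_genes:
            raise ValueError("mito_mode='ngenes' needs mitochondrial genes in the matrix")
        B = adata[:, mito_genes].X > 0
        mito_load = np.asarray(B.sum(axis=1)).ravel().astype(float)
    else:
        raise ValueError("mito_mode must be 'fraction' or 'ngenes'")

    report = QCReport(
        thresholds={
            "feature_threshold": feature_multiplier * med_feat,
            "median_features": med_feat,
            "mito_mode": mito_mode,
        }
    )
    med_mito = float(np.median(mito_load))
    if med_mito == 0.0:
        warnings.warn("median mitochondrial load is zero; mito rule skipped")
        report.notes.append("mito rule skipped: zero median load")
        mito_bad = np.zeros(adata.n_obs, dtype=bool)
    else:
        mito_bad = mito_load > mito_multiplier * med_mito
        report.thresholds["mito_threshold"] = mito_multiplier * med_mito
        report.thresholds["median_mito"] = med_mito

    report.n_cells_doublet = int(doublet.sum())
    report.n_cells_mito = int(mito_bad.sum())
    keep = ~(doublet | mito_bad)
    out = adata[keep].copy()
    if out.n_obs == 0:
        report.empty_output = True
    return out, report


def normalize_cp10k_log(adata: AnnData) -> AnnData:
    """log1p counts-per-10,000 normalization.

    value(c, g) = log1p(count(c, g) / total(c) * 1e4).  Cells with zero total
    counts get all-zero rows and a warning.  Raw counts are kept in
    ``layers['counts']``.
    """
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    X = X.astype(np.float64).tocsr()
    totals = np.asarray(X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        warnings.warn(f"{int((totals == 0).sum())} cell(s) with zero total counts")
    scale = np.divide(1e4, totals, out=np.zeros_like(totals), where=totals > 0)
    norm = sp.diags(scale) @ X
    norm.data = np.log1p(norm.data)
    out = AnnData(X=norm.tocsr(), obs=adata.obs.copy(), var=adata.var.copy())
    out.layers["counts"] = adata.X.copy()
    return out


def pct_expressing(nm: AnnData, cells, gene: str) -> float:
    """Fraction of the given cell subset with expression value > 0.

    ``cells`` is a boolean mask or an index/label selection over ``nm``.
    """
    v = gene_vector(nm, gene)
    if isinstance(cells, np.ndarray) and cells.dtype == bool:
        sub = v[cells]
    else:
        sub = v[nm.obs_names.get_indexer(list(cells))]
    if sub.size == 0:
        raise ValueError("empty cell subset")
    return float(np.mean(sub > 0))
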
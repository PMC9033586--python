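"""Small shared helpers for working with AnnData expression containers."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from anndata import AnnData


def gene_vector(adata: AnnData, gene: str) -> np.ndarray:
    """Dense 1-D expression vector for one gene (cells,)."""
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} not in the gene universe")
    col = adata[:, gene].X
    if sp.issparse(col):
        col = col.toarray()
    return np.asarray(col).ravel()


def dense_matrix(adata: AnnData) -> np.ndarray:
    X = adata.X
    if sp.issparse(X):
        return X.toarray()
    return np.asarray(X)


def expressing_fraction(adata: AnnData, gene: str, mask: np.ndarray | None = None) -> float:
    """Fraction of (masked) cells with expression value > 0 for `gene`."""
    v = gene_vector(adata, gene)
    if mask is not None:
        v = v[mask]
    if v.size == 0:
        raise ValueError("empty cell subset")
    return float(np.mean(v > 0))
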
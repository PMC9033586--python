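import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData


def make_adata(values, genes=None, obs=None, counts=True):
    """AnnData from a dense (cells x genes) array.

    With counts=True the values are stored as integer counts; otherwise they
    are taken as already-normalized expression values.
    """
    values = np.asarray(values)
    n, g = values.shape
    genes = list(genes) if genes is not None else [f"G{j:03d}" for j in range(g)]
    if obs is None:
        obs = pd.DataFrame(index=[f"c{i:03d}" for i in range(n)])
    dtype = np.int64 if counts else np.float64
    return AnnData(
        X=sp.csr_matrix(values.astype(dtype)),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes)),
    )


@pytest.fixture(scope="session")
def nhc_null():
    """A small stromal dataset with no planted effects."""
    import lnstroma as ln

    cfg = ln.SimConfig(n_genes=200, cells_per_subcluster=40, seed=101)
    adata, obs, truth = ln.generate_nhc_dataset(cfg)
    return adata, obs, truth


@pytest.fixture(scope="session")
def nhc_null_norm(nhc_null):
    import lnstroma as ln

    adata, _, _ = nhc_null
    return ln.normalize_cp10k_log(adata)
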
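"""Quality control and normalization.

Applies the atlas QC rules in their fixed order — genes detected in fewer
than 3 cells, cells expressing fewer than 200 genes, then the median-derived
doublet (> 3x median detected genes) and mitochondrial (> 2x median load)
rules — and normalizes to log1p counts-per-10,000.
"""

import numpy as np

import lnstroma as ln
from lnstroma.simulate import SimConfig

adata, _, _ = ln.generate_nhc_dataset(SimConfig(n_genes=400, cells_per_subcluster=40, seed=2))
print(f"input: {adata.shape[0]} cells x {adata.shape[1]} genes")

# the synthetic gene universe is small, so the min-genes rule is scaled down
filtered, report1 = ln.filter_genes_cells(adata, min_cells=3, min_genes=100)
print(f"gene/cell filter: removed {report1.n_genes_removed} genes, "
      f"{report1.n_cells_low_count} low-complexity cells")

filtered, report2 = ln.doublet_mito_filter(filtered)
print(f"doublet rule removed {report2.n_cells_doublet} cells "
      f"(threshold {report2.thresholds['feature_threshold']:.0f} detected genes); "
      f"mito rule removed {report2.n_cells_mito} cells")

nm = ln.normalize_cp10k_log(filtered)
sums = np.expm1(nm.X.toarray()).sum(axis=1)
print(f"normalized: per-cell expm1 sums = {sums.min():.1f}..{sums.max():.1f} "
      "(each retained cell is rescaled to exactly 10,000 counts before log1p)")
print(f"fraction of cells expressing G0001: "
      f"{ln.pct_expressing(nm, np.ones(nm.n_obs, bool), 'G0001'):.2f}")
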
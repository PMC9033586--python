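"""Rank-based gene-set enrichment scoring.

The score of a gene set S in one expression profile is

    (mean rank of S genes - mean rank of all genes) / SD of all ranks,

with ranks ascending in expression and ties averaged.  It is invariant to any
monotone rescaling of the profile, zero when S is the whole universe, and
maximal when the S genes occupy the top |S| ranks.  This is a light-weight
rank z-score used for per-cell malignant-signature scoring and per-patient
bulk signature scoring.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.stats import rankdata


def rank_zscore(values: np.ndarray, set_mask: np.ndarray) -> np.ndarray:
    """Rank z-scores for each row of ``values`` (profiles x genes).

    ``set_mask`` is a boolean vector over genes marking the set members.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    set_mask = np.asarray(set_mask, dtype=bool)
    if set_mask.sum() == 0:
        raise ValueError("empty gene set")
    if values.shape[1] != set_mask.size:
        raise ValueError("gene-set mask does not match the gene dimension")
    ranks = rankdata(values, axis=1)
    mean_all = ranks.mean(axis=1)
    sd_all = ranks.std(axis=1)
    mean_set = ranks[:, set_mask].mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(sd_all > 0, (mean_set - mean_all) / sd_all, 0.0)
    return score


def resolve_gene_set(
    universe: Sequence[str], gene_set: Sequence[str], min_overlap_frac: float = 0.5
) -> np.ndarray:
    """Boolean mask of ``gene_set`` over ``universe``; errors if the overlap
    falls below ``min_overlap_frac`` of the set (or is empty)."""
    gene_set = list(dict.fromkeys(gene_set))
    if not gene_set:
        raise ValueError("empty gene set")
    idx = {g: i for i, g in enumerate(universe)}
    present = [g for g in gene_set if g in idx]
    if not present:
        raise ValueError("gene set entirely absent from the universe")
    if len(present) / len(gene_set) < min_overlap_frac:
        raise ValueError(
            f"only {len(present)}/{len(gene_set)} gene-set members present "
            f"(need >= {min_overlap_frac:.0%})"
        )
    mask = np.zeros(len(universe), dtype=bool)
    mask[[idx[g] for g in present]] = True
    return mask
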
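"""Permutation-based ligand–receptor interaction screening.

For each ligand–receptor pair and each (sender subcluster, malignant B-cell
receiver) combination within one sample, the mean interaction score is the
average ligand expression in the sender multiplied by the average receptor
expression in the receiver (on the linear CP10K scale by default).  A pair is
scored only when the ligand is expressed in >20% of sender cells and the
receptor in >20% of receiver cells.  Significance comes from a permutation
null: cluster labels of all input cells are shuffled (1,000 times by default,
one shared set of shuffles for all pairs) and the p-value is the fraction of
permuted scores at least as large as the observed one, clamped below at
1/n_perm.

Across samples, interactions are retained when significant (p < alpha) in
strictly more than half of the samples and when the stroma-side gene is
upregulated in the sender subcluster in disease vs control; per-sample
p-values are combined with Fisher's method and corrected across retained
interactions with the Benjamini–Hochberg procedure.  Mean scores are averaged
across samples and min-max normalized across senders within each pair.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lnstroma.de import DEGSet

RESULT_COLUMNS = [
    "ligand",
    "receptor",
    "sender",
    "receiver",
    "sample_id",
    "mean_score",
    "p",
    "filtered",
]


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def mean_interaction_score(
    nm: AnnData,
    pair: tuple[str, str],
    sender_cells: np.ndarray,
    receiver_cells: np.ndarray,
    *,
    min_pct: float | None = 0.2,
    use_log: bool = False,
) -> float | None:
    """Mean interaction score for one pair between two cell subpopulations.

    Returns ``None`` when the pair fails the expression filter (ligand must be
    expressed in > ``min_pct`` of sender cells and receptor in > ``min_pct``
    of receiver cells; pass ``min_pct=None`` to skip the filter).  ``use_log``
    computes means on the log1p scale instead of the linear CP10K scale.
    """
    ligand, receptor = pair
    if sender_cells.sum() == 0 or receiver_cells.sum() == 0:
        raise ValueError("empty subpopulation")
    lig = _dense(nm[sender_cells, [ligand]].X).ravel()
    rec = _dense(nm[receiver_cells, [receptor]].X).ravel()
    if min_pct is not None and (np.mean(lig > 0) <= min_pct or np.mean(rec > 0) <= min_pct):
        return None
    if not use_log:
        lig, rec = np.expm1(lig), np.expm1(rec)
    return float(lig.mean() * rec.mean())


def _label_codes(labels: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    cats = pd.Categorical(list(labels))
    return cats.codes.astype(np.int64), list(cats.categories)


def _permuted_means(
    X: np.ndarray, counts: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Cluster-mean matrices under label permutation.

    Permuting cluster labels is equivalent to handing each cluster a uniform
    random subset of cells of its original size, realised here by shuffling the
    cell order and slicing consecutive blocks.  Returns (n_perm, n_clusters,
    n_genes).
    """
    n = X.shape[0]
    bounds = np.concatenate([[0], np.cumsum(counts)])
    out = np.empty((n_perm, counts.size, X.shape[1]))
    for t in range(n_perm):
        cs = np.vstack([np.zeros((1, X.shape[1])), X[rng.permutation(n)].cumsum(axis=0)])
        out[t] = (cs[bounds[1:]] - cs[bounds[:-1]]) / counts[:, None]
    return out


def permutation_pvalue(
    nm: AnnData,
    pair: tuple[str, str],
    labels: Sequence[str],
    sender: str,
    receiver: str,
    *,
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
    use_log: bool = False,
) -> float:
    """Permutation p-value of one pair's mean interaction score.

    ``labels`` assigns every cell of ``nm`` to a cluster; all labels are
    shuffled together.  With ``exhaustive`` the null is enumerated over every
    distinct label permutation (small inputs only) instead of sampled.
    """
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("degenerate labelling: all cells share one label")
    if not exhaustive and n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ligand, receptor = pair
    X = _dense(nm[:, [ligand, receptor]].X)
    if not use_log:
        X = np.expm1(X)
    lab = np.asarray(labels)

    def score(assign: np.ndarray) -> float:
        return X[assign == sender, 0].mean() * X[assign == receiver, 1].mean()

    obs = score(lab)
    if exhaustive:
        perms = sorted(set(itertools.permutations(lab)))
        null = np.array([score(np.asarray(p)) for p in perms])
        return float(np.mean(null >= obs - 1e-12))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += score(lab[rng.permutation(lab.size)]) >= obs - 1e-12
    return max(count / n_perm, 1.0 / n_perm)


def sample_interaction_analysis(
    nm: AnnData,
    lr_table: pd.DataFrame,
    *,
    receiver: str = "B_malignant",
    senders: Sequence[str] | None = None,
    cluster_key: str = "subcluster",
    n_perm: int = 1000,
    seed: int = 0,
    min_pct: float = 0.2,
    alpha_clamp: bool = True,
    use_log: bool = False,
) -> pd.DataFrame:
    """Score every (pair, sender) combination against one receiver in one sample.

    One shared set of ``n_perm`` label shuffles serves all pairs.  Pairs whose
    ligand or receptor is absent from the matrix, or that fail the >``min_pct``
    expression filter, are emitted with ``filtered=True`` and no p-value.
    """
    sample_ids = nm.obs["sample_id"].unique() if "sample_id" in nm.obs else ["sample"]
    if len(sample_ids) != 1:
        raise ValueError("sample_interaction_analysis expects cells of a single sample")
    sample_id = str(sample_ids[0])

    labels = nm.obs[cluster_key].astype(str)
    codes, cats = _label_codes(labels)
    if receiver not in cats:
        raise ValueError(f"receiver cluster {receiver!r} absent from the sample")
    if senders is None:
        senders = [c for c in cats if c != receiver]
    genes_used = sorted(
        {g for g in pd.concat([lr_table.ligand, lr_table.receptor]) if g in nm.var_names}
    )
    gi = {g: k for k, g in enumerate(genes_used)}
    X = _dense(nm[:, genes_used].X)
    if not use_log:
        X = np.expm1(X)

    counts = np.bincount(codes, minlength=len(cats))
    sums = np.zeros((len(cats), X.shape[1]))
    np.add.at(sums, codes, X)
    obs_means = sums / counts[:, None]
    obs_pct = np.zeros_like(obs_means)
    np.add.at(obs_pct, codes, (X > 0).astype(float))
    obs_pct /= counts[:, None]

    # shared permutation null: cells re-dealt to clusters of fixed sizes
    order = np.argsort(codes, kind="stable")
    rng = np.random.default_rng(seed)
    null_means = _permuted_means(X[order], counts, n_perm, rng)

    rows = []
    cat_idx = {c: k for k, c in enumerate(cats)}
    r = cat_idx[receiver]
    for _, row in lr_table.iterrows():
        lig, rec = row["ligand"], row["receptor"]
        present = lig in gi and rec in gi
        for s_name in senders:
            s = cat_idx[s_name]
            entry = {
                "ligand": lig,
                "receptor": rec,
                "sender": s_name,
                "receiver": receiver,
                "sample_id": sample_id,
                "mean_score": np.nan,
                "p": np.nan,
                "filtered": True,
            }
            if present:
                passes = (
                    obs_pct[s, gi[lig]] > min_pct and obs_pct[r, gi[rec]] > min_pct
                )
                if passes:
                    obs = obs_means[s, gi[lig]] * obs_means[r, gi[rec]]
                    null = null_means[:, s, gi[lig]] * null_means[:, r, gi[rec]]
                    p = float(np.mean(null >= obs - 1e-12))
                    if alpha_clamp:
                        p = max(p, 1.0 / n_perm)
                    entry.update(mean_score=float(obs), p=p, filtered=False)
            rows.append(entry)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def per_sample_screen(
    results: pd.DataFrame, n_samples: int | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Keep (pair, sender) combinations significant in > half of the samples.

    Samples without a (scored) result for a combination count as
    non-significant.  Returns one row per retained combination with its
    ``n_significant_samples``.
    """
    if n_samples is None:
        n_samples = results["sample_id"].nunique()
    scored = results[~results["p"].isna()]
    grp = scored.groupby(["ligand", "receptor", "sender"], sort=False)
    n_sig = grp["p"].apply(lambda p: int((p < alpha).sum()))
    coverage = grp["sample_id"].nunique()
    short = coverage[coverage < n_samples]
    if len(short):
        warnings.warn(
            f"{len(short)} interaction(s) scored in fewer than {n_samples} samples; "
            "missing samples counted as non-significant"
        )
    kept = n_sig[n_sig > n_samples / 2.0]
    out = kept.rename("n_significant_samples").reset_index()
    return out


def upregulation_filter(
    candidates: pd.DataFrame,
    deg_records: pd.DataFrame | Sequence[DEGSet],
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Keep candidates whose stroma-side (ligand) gene is upregulated in the
    sender subcluster in disease vs control (log_fc > 0 and adjusted rank-sum
    p < ``alpha``).  Candidates whose sender subcluster has no DE results are
    dropped with a warning.
    """
    if not isinstance(deg_records, pd.DataFrame):
        deg_records = pd.concat([ds.records for ds in deg_records], ignore_index=True)
    covered = set(deg_records["subcluster"])
    up = deg_records[(deg_records.log_fc > 0) & (deg_records.padj_rank < alpha)]
    up_keys = set(zip(up.gene, up.subcluster))
    missing = sorted(set(candidates["sender"]) - covered)
    if missing:
        warnings.warn(f"no DE results for sender subcluster(s) {missing}; dropped")
    keep = [
        (lig, snd) in up_keys
        for lig, snd in zip(candidates["ligand"], candidates["sender"])
    ]
    out = candidates[np.asarray(keep, dtype=bool)].reset_index(drop=True)
    out = out.assign(upregulated=True)
    return out


def fisher_combine(pvalues: Sequence[float]) -> tuple[float, float]:
    """Fisher's method: chi2 = -2 sum(ln p) on 2k degrees of freedom."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1] (clamp permutation zeros upstream)")
    chi2 = float(-2.0 * np.sum(np.log(p)))
    return chi2, float(stats.chi2.sf(chi2, 2 * p.size))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def integrate(candidates: pd.DataFrame, per_sample_results: pd.DataFrame) -> pd.DataFrame:
    """Meta-integrate retained candidates across samples.

    Per (pair, sender): the mean of per-sample mean scores, Fisher combination
    of the per-sample p-values, min-max normalization of the mean score across
    senders within each pair (a single sender normalizes to 1.0), and
    Benjamini–Hochberg adjustment of the combined p-values across all retained
    combinations.
    """
    if candidates.empty:
        return pd.DataFrame(
            columns=[
                "ligand", "receptor", "sender", "n_significant_samples", "mean_score",
                "normalized_score", "fisher_chi2", "combined_p", "adj_p", "upregulated",
            ]
        )
    scored = per_sample_results[~per_sample_results["p"].isna()]
    rows = []
    for _, cand in candidates.iterrows():
        sub = scored[
            (scored.ligand == cand.ligand)
            & (scored.receptor == cand.receptor)
            & (scored.sender == cand.sender)
        ]
        chi2, comb = fisher_combine(sub["p"])
        if len(sub) == 1:
            warnings.warn("single-sample candidate: Fisher combination with k = 1")
        rows.append(
            {
                "ligand": cand.ligand,
                "receptor": cand.receptor,
                "sender": cand.sender,
                "n_significant_samples": cand.get("n_significant_samples", len(sub)),
                "mean_score": float(sub["mean_score"].mean()),
                "fisher_chi2": chi2,
                "combined_p": comb,
                "upregulated": bool(cand.get("upregulated", True)),
            }
        )
    out = pd.DataFrame(rows)
    normalized = np.ones(len(out))
    for _, idx in out.groupby(["ligand", "receptor"]).groups.items():
        vals = out.loc[idx, "mean_score"].to_numpy()
        span = vals.max() - vals.min()
        normalized[out.index.get_indexer(idx)] = (
            (vals - vals.min()) / span if span > 0 else 1.0
        )
    out["normalized_score"] = normalized
    out["adj_p"] = bh_adjust(out["combined_p"])
    cols = [
        "ligand", "receptor", "sender", "n_significant_samples", "mean_score",
        "normalized_score", "fisher_chi2", "combined_p", "adj_p", "upregulated",
    ]
    return out[cols]


def integrate_interactions(
    per_sample_results: pd.DataFrame,
    deg_records: pd.DataFrame | Sequence[DEGSet],
    *,
    n_samples: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full meta-integration: sample screen -> upregulation filter -> integrate."""
    candidates = per_sample_screen(per_sample_results, n_samples, alpha)
    candidates = upregulation_filter(candidates, deg_records, alpha=alpha)
    return integrate(candidates, per_sample_results)
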
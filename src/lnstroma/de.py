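"""Differential expression with a dual-test consensus and confounder subtraction.

Genes are tested per subcluster between two groups of cells (disease cohort
FL vs MFLN, anatomical site mLN vs pLN, or one cluster vs the rest) with two
independent tests: the Wilcoxon rank-sum test and a two-part hurdle model with
a cellular-detection-rate covariate.  A gene is a consensus DEG when both
Bonferroni-adjusted p-values are < 0.05.

Because mesenteric and peripheral lymph nodes differ transcriptionally on
their own, FL-vs-control DEG lists are cleaned by subtracting genes that are
also differentially expressed between mLN and pLN control samples
(:func:`confounder_subtract`), optionally cross-checked by re-running the
cohort comparison on peripheral-site samples only
(:func:`pln_only_confirmation`).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from anndata import AnnData
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

LOGFC_PSEUDOCOUNT = 1e-9
EXACT_MAX_N = 8

DEG_COLUMNS = [
    "gene",
    "subcluster",
    "log_fc",
    "pct1",
    "pct2",
    "p_rank",
    "padj_rank",
    "p_hurdle",
    "padj_hurdle",
    "consensus",
]


@dataclass
class DEGSet:
    """A set of per-gene DE results for one comparison axis and subcluster."""

    axis: str  # "cohort" | "site" | "cluster"
    subcluster: str
    records: pd.DataFrame
    direction: str = "both"
    group1: str = ""
    group2: str = ""
    removed_genes: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    def up(self) -> "DEGSet":
        """Consensus DEGs upregulated in group1 (log_fc > 0)."""
        rec = self.records[(self.records.consensus) & (self.records.log_fc > 0)]
        return DEGSet(
            axis=self.axis,
            subcluster=self.subcluster,
            records=rec.reset_index(drop=True),
            direction="up",
            group1=self.group1,
            group2=self.group2,
        )


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value with tie correction.

    Exact enumeration over all rank assignments when both groups have <= 8
    observations, tie-corrected continuity-corrected normal approximation
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    if a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N:
        ranks = stats.rankdata(pooled)
        w_obs = ranks[: a.size].sum()
        sums = np.array(
            [sum(c) for c in itertools.combinations(ranks, a.size)]
        )
        lo = np.mean(sums <= w_obs + 1e-9)
        hi = np.mean(sums >= w_obs - 1e-9)
        return float(min(1.0, 2.0 * min(lo, hi)))
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def _lr_chi2_logit(det: np.ndarray, g: np.ndarray, covar: np.ndarray | None):
    """LR chi-square for the group term in a logistic detection model."""
    base = [np.ones_like(g)]
    if covar is not None:
        base.append(covar)
    X_red = np.column_stack(base)
    X_full = np.column_stack(base + [g])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.Logit(det, X_full).fit(disp=0, maxiter=200)
        red = sm.Logit(det, X_red).fit(disp=0, maxiter=200)
    if not np.all(np.isfinite(full.params)) or np.any(np.abs(full.params) > 25):
        raise np.linalg.LinAlgError("separation")
    return max(0.0, 2.0 * (full.llf - red.llf))


def _corrected_detection_chi2(det: np.ndarray, g: np.ndarray) -> float:
    """Haldane (+0.5) continuity-corrected 2x2 LR chi-square, used when the
    logistic fit is perfectly separated."""
    tab = np.array(
        [
            [np.sum((g == 0) & (det == 1)), np.sum((g == 0) & (det == 0))],
            [np.sum((g == 1) & (det == 1)), np.sum((g == 1) & (det == 0))],
        ],
        dtype=float,
    )
    tab += 0.5
    exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
    return float(2.0 * np.sum(tab * np.log(tab / exp)))


def hurdle_test(a, b, cdr_a=None, cdr_b=None, *, full_output: bool = False):
    """Two-part (hurdle) test of differential expression.

    Part one models detection (value > 0) with a logistic regression on group
    membership plus an optional per-cell detection-rate covariate; part two
    models the positive expression values with a Gaussian linear model on the
    same design.  The likelihood-ratio chi-squares of the group term are
    summed, with summed degrees of freedom, into one p-value.

    On complete separation in the logistic part a continuity-corrected 2x2
    likelihood-ratio statistic replaces it, with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 cells per group")
    y = np.concatenate([a, b])
    g = np.concatenate([np.zeros(a.size), np.ones(b.size)])
    covar = None
    if cdr_a is not None and cdr_b is not None:
        covar = np.concatenate([np.asarray(cdr_a, float), np.asarray(cdr_b, float)])
        if np.std(covar) == 0:
            covar = None
        else:
            covar = (covar - covar.mean()) / covar.std()

    det = (y > 0).astype(float)
    chi2_d, df_d = 0.0, 0
    if 0 < det.sum() < det.size:
        per_group_const = (det[g == 0].std() == 0) and (det[g == 1].std() == 0)
        try:
            if per_group_const:
                raise np.linalg.LinAlgError("separation")
            chi2_d = _lr_chi2_logit(det, g, covar)
        except (np.linalg.LinAlgError, PerfectSeparationError, ValueError, RuntimeError):
            warnings.warn("logistic part separated; using continuity-corrected table")
            chi2_d = _corrected_detection_chi2(det, g)
        df_d = 1

    chi2_c, df_c = 0.0, 0
    pos = y > 0
    if np.sum(pos & (g == 0)) >= 2 and np.sum(pos & (g == 1)) >= 2 and np.std(y[pos]) > 0:
        base = [np.ones(int(pos.sum()))]
        if covar is not None:
            zc = covar[pos]
            if np.std(zc) > 0:
                base.append(zc)
        X_red = np.column_stack(base)
        X_full = np.column_stack(base + [g[pos]])
        full = sm.OLS(y[pos], X_full).fit()
        red = sm.OLS(y[pos], X_red).fit()
        chi2_c = max(0.0, 2.0 * (full.llf - red.llf))
        df_c = 1

    df = df_d + df_c
    p = float(stats.chi2.sf(chi2_d + chi2_c, df)) if df > 0 else 1.0
    if full_output:
        return {"p": p, "chi2_disc": chi2_d, "chi2_cont": chi2_c, "df": df,
                "p_disc": float(stats.chi2.sf(chi2_d, 1)) if df_d else 1.0,
                "p_cont": float(stats.chi2.sf(chi2_c, 1)) if df_c else 1.0}
    return p


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def _group_masks(obs: pd.DataFrame, axis: str, subcluster: str, site_within_cohort):
    sub = (obs["subcluster"] == subcluster).to_numpy()
    if axis == "cohort":
        g1 = sub & (obs["cohort"] == "FL").to_numpy()
        g2 = sub & (obs["cohort"] == "MFLN").to_numpy()
        labels = ("FL", "MFLN")
    elif axis == "site":
        base = sub
        if site_within_cohort is not None:
            base = base & (obs["cohort"] == site_within_cohort).to_numpy()
        g1 = base & (obs["site"] == "mLN").to_numpy()
        g2 = base & (obs["site"] == "pLN").to_numpy()
        labels = ("mLN", "pLN")
    elif axis == "cluster":
        g1 = sub
        g2 = ~sub
        labels = (subcluster, "rest")
    else:
        raise ValueError(f"unknown axis {axis!r}")
    return g1, g2, labels


def find_degs(
    nm: AnnData,
    axis: str,
    subcluster: str,
    *,
    min_pct: float = 0.2,
    min_logfc: float = 0.25,
    alpha: float = 0.05,
    site_within_cohort: str | None = "MFLN",
    use_cdr: bool = True,
    bonferroni_family: str = "all",
) -> DEGSet:
    """Dual-test differential expression for one subcluster and axis.

    Genes are pre-filtered: tested only when expressed in at least ``min_pct``
    of cells in at least one group and |log fold-change| >= ``min_logfc``
    (natural-log ratio of mean expm1 expression with a small pseudocount).
    Bonferroni correction uses all genes in the matrix by default
    (``bonferroni_family="all"``, matching the convention of mainstream
    single-cell toolkits and keeping the correction honest about the
    data-dependent pre-filter; ``"tested"`` restricts the family to the genes
    that passed the pre-filters).  ``consensus`` requires both adjusted
    p-values < ``alpha``.

    For ``axis="site"`` the comparison is restricted to the
    ``site_within_cohort`` cohort (control samples by default) so that site
    differences are profiled free of disease effects.
    """
    g1, g2, labels = _group_masks(nm.obs, axis, subcluster, site_within_cohort)
    empty = DEGSet(
        axis=axis,
        subcluster=subcluster,
        records=pd.DataFrame(columns=DEG_COLUMNS),
        group1=labels[0],
        group2=labels[1],
    )
    if g1.sum() == 0 or g2.sum() == 0:
        warnings.warn(
            f"subcluster {subcluster!r} missing in one group for axis {axis!r}; skipped"
        )
        empty.notes.append("skipped: subcluster absent in one group")
        return empty

    A = _dense(nm[g1].X)
    B = _dense(nm[g2].X)
    pct1 = (A > 0).mean(axis=0)
    pct2 = (B > 0).mean(axis=0)
    mean1 = np.expm1(A).mean(axis=0)
    mean2 = np.expm1(B).mean(axis=0)
    log_fc = np.log(mean1 + LOGFC_PSEUDOCOUNT) - np.log(mean2 + LOGFC_PSEUDOCOUNT)
    tested = ((pct1 >= min_pct) | (pct2 >= min_pct)) & (np.abs(log_fc) >= min_logfc)
    m = int(tested.sum())
    if m == 0:
        empty.notes.append("no genes passed the pre-filters")
        return empty

    idx = np.flatnonzero(tested)
    At, Bt = A[:, idx], B[:, idx]
    small = A.shape[0] <= EXACT_MAX_N and B.shape[0] <= EXACT_MAX_N
    if small:
        p_rank = np.array([rank_sum_test(At[:, j], Bt[:, j]) for j in range(m)])
    else:
        with np.errstate(all="ignore"):
            res = stats.mannwhitneyu(
                At, Bt, alternative="two-sided", method="asymptotic", axis=0
            )
        p_rank = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)

    cdr_a = cdr_b = None
    if use_cdr:
        cdr_a = (A > 0).mean(axis=1)
        cdr_b = (B > 0).mean(axis=1)
    p_hurdle = np.array(
        [hurdle_test(At[:, j], Bt[:, j], cdr_a, cdr_b) for j in range(m)]
    )

    if bonferroni_family == "all":
        m_corr = nm.n_vars
    elif bonferroni_family == "tested":
        m_corr = m
    else:
        raise ValueError("bonferroni_family must be 'all' or 'tested'")
    records = pd.DataFrame(
        {
            "gene": np.asarray(nm.var_names)[idx],
            "subcluster": subcluster,
            "log_fc": log_fc[idx],
            "pct1": pct1[idx],
            "pct2": pct2[idx],
            "p_rank": p_rank,
            "padj_rank": np.minimum(1.0, p_rank * m_corr),
            "p_hurdle": p_hurdle,
            "padj_hurdle": np.minimum(1.0, p_hurdle * m_corr),
        }
    )
    records["consensus"] = (records.padj_rank < alpha) & (records.padj_hurdle < alpha)
    return DEGSet(
        axis=axis,
        subcluster=subcluster,
        records=records,
        group1=labels[0],
        group2=labels[1],
    )


def confounder_subtract(
    cohort_up: DEGSet, site_degs: DEGSet, *, direction_matched: bool = False
) -> DEGSet:
    """Remove anatomical-site DEGs from a cohort-upregulated DEG set.

    ``cohort_up`` must be the FL-upregulated set (axis cohort, direction up);
    ``site_degs`` the site-axis results for the same subcluster.  By default
    any consensus site DEG is removed regardless of direction (conservative);
    with ``direction_matched`` only site DEGs upregulated in the same direction
    are removed.  Provenance of the removed genes is kept on the result.
    """
    if cohort_up.axis != "cohort" or cohort_up.direction != "up":
        raise ValueError("first argument must be a cohort-axis, direction-up DEG set")
    if site_degs.axis != "site":
        raise ValueError("second argument must be a site-axis DEG set")
    if cohort_up.subcluster != site_degs.subcluster:
        raise ValueError(
            f"subcluster mismatch: {cohort_up.subcluster!r} vs {site_degs.subcluster!r}"
        )
    site_rec = site_degs.records[site_degs.records["consensus"].astype(bool)]
    if direction_matched:
        site_rec = site_rec[site_rec.log_fc > 0]
    confounded = set(site_rec.gene)
    keep = ~cohort_up.records.gene.isin(confounded)
    removed = sorted(set(cohort_up.records.gene[~keep]))
    return DEGSet(
        axis="cohort",
        subcluster=cohort_up.subcluster,
        records=cohort_up.records[keep].reset_index(drop=True),
        direction="up",
        group1=cohort_up.group1,
        group2=cohort_up.group2,
        removed_genes=removed,
    )


def pln_only_confirmation(nm: AnnData, subcluster: str, **kwargs) -> DEGSet:
    """Cohort DEG analysis using peripheral-LN samples only (cross-check)."""
    pl = (nm.obs["site"] == "pLN").to_numpy()
    for cohort in ("FL", "MFLN"):
        if not np.any(pl & (nm.obs["cohort"] == cohort).to_numpy()):
            raise ValueError(f"no pLN samples in cohort {cohort}")
    return find_degs(nm[pl].copy(), "cohort", subcluster, **kwargs)


def deg_counts(degsets) -> pd.DataFrame:
    """Per-subcluster counts of consensus upregulated genes."""
    rows = []
    for ds in degsets:
        rec = ds.records
        n_up = int(((rec.consensus) & (rec.log_fc > 0)).sum()) if len(rec) else 0
        rows.append({"subcluster": ds.subcluster, "n_up": n_up})
    return pd.DataFrame(rows)
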
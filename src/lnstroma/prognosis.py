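"""Stroma-specific prognostic marker screening in bulk survival cohorts.

The screen takes disease-upregulated stromal DEGs, keeps those with a log
fold-change > 0.5 that are essentially silent in haematopoietic cells
(< 0.1% of cells expressing), dichotomizes each candidate's bulk expression at
the cutpoint maximizing the standardized two-group log-rank statistic
(maximally selected rank statistics), tests high-vs-low survival with
Kaplan–Meier curves and the log-rank test, screens candidates by comparing
the proportion of high-expression patients between outcome-defined favourable
(alive 10 years after diagnosis) and unfavourable (died within 5 years)
groups, and finally adjusts survivors for the IPI clinical covariate in a
multivariate Cox proportional-hazards model.  A stromal signature can be
extracted with additional endothelial-specificity filters and scored per
patient with a rank-based enrichment statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from lnstroma._utils import expressing_fraction
from lnstroma.de import DEGSet
from lnstroma.scoring import rank_zscore, resolve_gene_set


@dataclass
class CutpointResult:
    gene: str
    cutpoint: float
    statistic: float  # max standardized log-rank statistic
    n_low: int
    n_high: int


@dataclass
class ScreenResult:
    gene: str
    cutpoint: float
    n_high_favourable: int
    n_favourable: int
    n_high_unfavourable: int
    n_unfavourable: int
    p: float
    prognostic: bool
    status: str = "ok"


def _check_cohort(cohort: pd.DataFrame) -> None:
    for col in ("patient_id", "time", "event"):
        if col not in cohort:
            raise ValueError(f"survival cohort lacks column {col!r}")
    if cohort["patient_id"].duplicated().any():
        raise ValueError("duplicate patient identifiers")
    if (cohort["time"] <= 0).any():
        raise ValueError("survival times must be positive")


def stroma_specific_candidates(
    deg_up: DEGSet | pd.DataFrame,
    haem_nm: AnnData,
    *,
    min_logfc: float = 0.5,
    max_haem_frac: float = 0.001,
) -> list[str]:
    """Disease-upregulated stromal genes that are silent in haematopoietic cells.

    Keeps genes with log fold-change > ``min_logfc`` whose expressing fraction
    among haematopoietic cells is < ``max_haem_frac``.  Genes absent from the
    haematopoietic matrix count as unexpressed (logged).
    """
    rec = deg_up.records if isinstance(deg_up, DEGSet) else deg_up
    rec = rec[rec.log_fc > min_logfc]
    out = []
    absent = []
    for gene in pd.unique(rec.gene):
        if gene in haem_nm.var_names:
            frac = expressing_fraction(haem_nm, gene)
        else:
            frac = 0.0
            absent.append(gene)
        if frac < max_haem_frac:
            out.append(gene)
    if absent:
        warnings.warn(
            f"{len(absent)} gene(s) absent from the haematopoietic matrix; treated as 0% expressing"
        )
    return sorted(out)


def _logrank_standardized(time, event, high) -> float:
    """|O - E| / sqrt(V) for the high group, hypergeometric variance."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    high = np.asarray(high, bool)
    o = e = v = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & high).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & high).sum()
        o += d1
        e += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v <= 0:
        return 0.0
    return abs(o - e) / np.sqrt(v)


def maxstat_cutpoint(
    cohort: pd.DataFrame, gene: str, minprop: float = 0.1, *, min_patients: int = 20
) -> CutpointResult:
    """Expression cutpoint by maximally selected rank statistics.

    Evaluates the standardized two-group log-rank statistic at every candidate
    cutpoint keeping at least ``minprop`` of patients on each side, and returns
    the (smallest) maximizing cutpoint.  ``min_patients`` guards against
    cohorts too small for a stable cutpoint; lower it only for toy inputs.
    """
    _check_cohort(cohort)
    n = len(cohort)
    if n < min_patients:
        raise ValueError(f"need at least {min_patients} patients")
    if cohort["event"].sum() < 1:
        raise ValueError("need at least one event")
    x = cohort[gene].to_numpy(dtype=float)
    candidates = np.unique(x)[:-1]  # cut at c: high = x > c
    admissible = [
        c
        for c in candidates
        if minprop * n <= np.sum(x > c) <= (1 - minprop) * n
    ]
    if not admissible:
        raise ValueError(f"no admissible cutpoint for gene {gene!r}")
    best_c, best_stat = None, -np.inf
    for c in admissible:
        s = _logrank_standardized(cohort["time"], cohort["event"], x > c)
        if s > best_stat + 1e-12:  # ties keep the smallest cutpoint
            best_c, best_stat = c, s
    return CutpointResult(
        gene=gene,
        cutpoint=float(best_c),
        statistic=float(best_stat),
        n_low=int(np.sum(x <= best_c)),
        n_high=int(np.sum(x > best_c)),
    )


def km_logrank(cohort: pd.DataFrame, grouping) -> tuple[float, float, dict]:
    """Kaplan–Meier curves and two-sided log-rank test for a binary grouping.

    Returns (chi-square, p, curves) where curves maps group label to the
    fitted survival function (a DataFrame indexed by time).
    """
    _check_cohort(cohort)
    grouping = np.asarray(grouping)
    groups = pd.unique(grouping)
    if len(groups) != 2 or min((grouping == g).sum() for g in groups) == 0:
        raise ValueError("need two non-empty groups")
    masks = {g: grouping == g for g in groups}
    for g, m in masks.items():
        if cohort.loc[m, "event"].sum() == 0:
            warnings.warn(f"group {g!r} has zero events")
    res = logrank_test(
        cohort.loc[masks[groups[0]], "time"],
        cohort.loc[masks[groups[1]], "time"],
        event_observed_A=cohort.loc[masks[groups[0]], "event"],
        event_observed_B=cohort.loc[masks[groups[1]], "event"],
    )
    curves = {}
    for g, m in masks.items():
        kmf = KaplanMeierFitter()
        kmf.fit(cohort.loc[m, "time"], cohort.loc[m, "event"], label=str(g))
        curves[g] = kmf.survival_function_
    return float(res.test_statistic), float(res.p_value), curves


def outcome_groups(cohort: pd.DataFrame) -> pd.Series:
    """Favourable / unfavourable / intermediate outcome partition.

    favourable: alive 10 years after diagnosis (death after >= 10 years, or
    censored with follow-up >= 10 years); unfavourable: died within 5 years;
    intermediate: everyone else.  The partition is exhaustive and mutually
    exclusive.
    """
    _check_cohort(cohort)
    time = cohort["time"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy(dtype=bool)
    lab = np.full(len(cohort), "intermediate", dtype=object)
    lab[time >= 10.0] = "favourable"
    lab[event & (time < 5.0)] = "unfavourable"
    return pd.Series(lab, index=cohort.index, name="outcome_group")


def outcome_group_screen(
    cohort: pd.DataFrame,
    gene: str,
    cutpoint: float,
    *,
    alpha: float = 0.05,
    two_sided: bool = False,
) -> ScreenResult:
    """Outcome-group proportion screen for one candidate gene.

    Compares the proportion of high-expression (> ``cutpoint``) patients
    between the unfavourable and favourable outcome groups with a Fisher exact
    test (one-sided for a higher proportion among unfavourable patients by
    default).  The gene is flagged prognostic when that proportion is
    significantly higher at ``alpha``.
    """
    groups = outcome_groups(cohort)
    high = cohort[gene].to_numpy(dtype=float) > cutpoint
    fav = groups == "favourable"
    unf = groups == "unfavourable"
    counts = dict(
        n_high_favourable=int(np.sum(high & fav)),
        n_favourable=int(fav.sum()),
        n_high_unfavourable=int(np.sum(high & unf)),
        n_unfavourable=int(unf.sum()),
    )
    if fav.sum() == 0 or unf.sum() == 0:
        return ScreenResult(
            gene=gene, cutpoint=cutpoint, p=float("nan"), prognostic=False,
            status="insufficient groups", **counts,
        )
    table = [
        [counts["n_high_unfavourable"], counts["n_unfavourable"] - counts["n_high_unfavourable"]],
        [counts["n_high_favourable"], counts["n_favourable"] - counts["n_high_favourable"]],
    ]
    alternative = "two-sided" if two_sided else "greater"
    _, p = stats.fisher_exact(table, alternative=alternative)
    unf_prop = counts["n_high_unfavourable"] / counts["n_unfavourable"]
    fav_prop = counts["n_high_favourable"] / counts["n_favourable"]
    return ScreenResult(
        gene=gene,
        cutpoint=cutpoint,
        p=float(p),
        prognostic=bool(p < alpha and unf_prop > fav_prop),
        **counts,
    )


def cox_adjusted(
    cohort: pd.DataFrame, gene_indicators: pd.DataFrame, *, ipi: bool = True
) -> pd.DataFrame:
    """Cox proportional-hazards fit of dichotomized gene indicators (+ IPI).

    ``gene_indicators`` holds one 0/1 column per gene (high expression at the
    maxstat cutpoint), indexed like ``cohort``.  Returns hazard ratios, 95%
    confidence intervals and Wald p-values per covariate.  Non-convergence is
    raised as an explicit error, never silently dropped.
    """
    _check_cohort(cohort)
    df = pd.DataFrame(
        {"time": cohort["time"].to_numpy(), "event": cohort["event"].to_numpy()}
    )
    for col in gene_indicators.columns:
        v = gene_indicators[col].to_numpy(dtype=float)
        if np.std(v) == 0:
            raise ValueError(f"covariate {col!r} has no variation")
        df[col] = v
    if ipi:
        if "ipi" not in cohort:
            raise ValueError("cohort lacks the 'ipi' covariate")
        df["ipi"] = cohort["ipi"].to_numpy(dtype=float)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception as err:  # lifelines ConvergenceError and kin
        raise RuntimeError(f"Cox model did not converge: {err}") from err
    summary = cph.summary
    return pd.DataFrame(
        {
            "covariate": summary.index,
            "hr": np.exp(summary["coef"].to_numpy()),
            "hr_lower95": np.exp(summary["coef lower 95%"].to_numpy()),
            "hr_upper95": np.exp(summary["coef upper 95%"].to_numpy()),
            "p": summary["p"].to_numpy(),
        }
    ).reset_index(drop=True)


def trc_signature_extract(
    deg_up: DEGSet | pd.DataFrame,
    haem_nm: AnnData,
    bec_nm: AnnData,
    lec_nm: AnnData,
    array_genes,
    *,
    max_haem_frac: float = 0.001,
    max_bec_frac: float = 0.10,
    max_lec_frac: float = 0.10,
) -> list[str]:
    """Extract a stromal (T-zone reticular cell) signature.

    Keeps disease-upregulated genes expressed in < 0.1% of haematopoietic
    cells, < 10% of blood endothelial cells and < 10% of lymphatic endothelial
    cells, and present on the bulk array.  An empty result is allowed.
    """
    rec = deg_up.records if isinstance(deg_up, DEGSet) else deg_up
    array_genes = set(array_genes)
    out = []
    for gene in pd.unique(rec.gene):
        if gene not in array_genes:
            continue

        def frac(nm: AnnData) -> float:
            return expressing_fraction(nm, gene) if gene in nm.var_names else 0.0

        if (
            frac(haem_nm) < max_haem_frac
            and frac(bec_nm) < max_bec_frac
            and frac(lec_nm) < max_lec_frac
        ):
            out.append(gene)
    if not out:
        warnings.warn("signature extraction returned no genes")
    return sorted(out)


def signature_enrichment(
    expression: pd.DataFrame, gene_list, *, min_overlap_frac: float = 1e-9
) -> pd.Series:
    """Per-patient rank z-score of a gene signature in bulk profiles.

    ``expression`` is patients x genes.  Requires at least one signature gene
    on the array.
    """
    mask = resolve_gene_set(list(expression.columns), list(gene_list), min_overlap_frac)
    scores = rank_zscore(expression.to_numpy(dtype=float), mask)
    return pd.Series(scores, index=expression.index, name="signature_score")
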
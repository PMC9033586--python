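"""Stroma-specific prognostic marker screen on a synthetic survival cohort.

Filters disease-upregulated stromal genes to those silent in haematopoietic
cells, dichotomizes candidate expression at the maximally-selected-rank-
statistic cutpoint, tests survival with Kaplan-Meier / log-rank, screens by
favourable (alive at 10 years) vs unfavourable (died within 5 years) outcome
groups, and adjusts the survivors for IPI in a multivariate Cox model.
"""

import warnings

import numpy as np
import pandas as pd

import lnstroma as ln
from lnstroma.simulate import SurvivalEffect

warnings.filterwarnings("ignore")

cohort = ln.generate_survival_cohort(
    300,
    [SurvivalEffect("LOX", np.log(2)), SurvivalEffect("PTGIS", 0.0)],
    censor_rate=0.3,
    seed=6,
)
print(f"cohort: {len(cohort)} patients, {int(cohort.event.sum())} deaths")

for gene in ("LOX", "PTGIS"):
    cut = ln.maxstat_cutpoint(cohort, gene)
    chi2, p, _ = ln.km_logrank(cohort, np.where(cohort[gene] > cut.cutpoint, "high", "low"))
    screen = ln.outcome_group_screen(cohort, gene, cut.cutpoint)
    print(f"\n{gene}: maxstat cutpoint {cut.cutpoint:.2f} "
          f"({cut.n_high} high / {cut.n_low} low)")
    print(f"  log-rank chi2 = {chi2:.1f}, p = {p:.2e}")
    print(f"  outcome screen: high-expression in {screen.n_high_unfavourable}/"
          f"{screen.n_unfavourable} unfavourable vs {screen.n_high_favourable}/"
          f"{screen.n_favourable} favourable patients "
          f"(one-sided p = {screen.p:.3g}) -> prognostic: {screen.prognostic}")

cut = ln.maxstat_cutpoint(cohort, "LOX")
indicators = pd.DataFrame({"LOX_high": (cohort.LOX > cut.cutpoint).astype(int)})
fit = ln.cox_adjusted(cohort, indicators)  # multivariate: gene + IPI
print("\nmultivariate Cox (hazard ratios, 95% CI):")
print(fit.round(3).to_string(index=False))
# LOX carries a planted hazard (true HR = 2 per log-expression unit) and
# survives the whole screen; PTGIS carries none and is not flagged.
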
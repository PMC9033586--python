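# lnstroma

Analysis toolkit for single-cell studies of the lymph-node stromal
compartment in follicular lymphoma (FL) and tumour-free control lymph nodes
(MFLN).  Lymph-node stroma — blood endothelial cells (BEC), lymphatic
endothelial cells (LEC) and non-endothelial stromal cells (NESC, including
T-zone reticular cells, follicular dendritic cells and marginal reticular
cells) — is reshaped by lymphoma, signals to malignant B cells, and carries
prognostic information that bulk tumour profiling misses.  `lnstroma`
implements the bespoke statistical machinery such a study needs, end to end,
together with a seeded synthetic-data generator that plants known effects so
every stage can be validated by ground-truth recovery.

## What it computes

**Quality control and normalization** (`lnstroma.qc`) — genes detected in
fewer than 3 cells and cells expressing fewer than 200 genes are removed;
cells with detected-gene counts > 3x the median (possible doublets) or
mitochondrial load > 2x the median (possible apoptotic cells) are dropped;
expression is normalized to `log1p(10^4 * counts / cell total)` (log CP10K).

**Malignant B-cell calling by light-chain restriction**
(`lnstroma.clonality`) — clonal B cells express a single immunoglobulin light
chain.  Per B-cell cluster, with `n_λ = #{cells: IGLC2 > 1}` and
`n_κ = #{cells: IGKC > 2}` on the log-CP10K scale, the cluster is called
malignant when `n_λ/n_κ > 2.0` (lambda-restricted) or `< 0.25`
(kappa-restricted); the polyclonal human background is roughly 60:40 κ:λ.
A rank z-score of a malignant-signature gene set corroborates the calls.

**Confounder-aware differential expression** (`lnstroma.de`) — per
subcluster, genes expressed in ≥ 20% of either group with |ln fold-change| ≥
0.25 are tested with the Wilcoxon rank-sum test (exact, tie-aware, for groups
of ≤ 8 cells) and an independent two-part hurdle model (logistic detection +
Gaussian positive-expression components, each with a cellular-detection-rate
covariate).  A consensus DEG needs Bonferroni-adjusted p < 0.05 from *both*
tests.  Because mesenteric (mLN) and peripheral (pLN) lymph nodes differ on
their own, disease DEG lists are cleaned by subtracting mLN-vs-pLN DEGs
profiled within control samples, with an optional pLN-only re-analysis as a
cross-check.

**Permutation ligand–receptor screening** (`lnstroma.interactions`) — for a
ligand–receptor pair between a stromal sender subcluster and a sample's
malignant B cells, the mean interaction score is
`mean(ligand expr in sender) x mean(receptor expr in receiver)` on the linear
CP10K scale, computed only when each gene is expressed in > 20% of its
subpopulation.  Cluster labels of all cells are shuffled 1,000 times to build
a null; `p = #{null ≥ observed}/1000`, clamped at 1/1000.  Across samples an
interaction is retained when significant in strictly more than half of them
and its stroma-side gene is disease-upregulated (log FC > 0, adjusted
p < 0.05); per-sample p-values are combined with Fisher's method
(`χ² = −2Σ ln pᵢ` on 2k df) and corrected by Benjamini–Hochberg, with mean
scores min-max normalized across senders within each pair.

**Stroma-specific prognostic screen** (`lnstroma.prognosis`) —
disease-upregulated stromal genes with ln FC > 0.5 expressed in < 0.1% of
haematopoietic cells are tested in a bulk survival cohort: expression is
dichotomized at the cutpoint maximizing the standardized log-rank statistic
(maximally selected rank statistics, exhaustive search within the 10–90%
quantile range), survival compared by Kaplan–Meier / two-sided log-rank, and
candidates screened by comparing the high-expression proportion between
outcome-defined groups (favourable: alive 10 years after diagnosis;
unfavourable: died within 5 years; Fisher exact, one-sided).  Survivors enter
a multivariate Cox proportional-hazards model with the IPI clinical
covariate.  A stromal signature (additional < 10% BEC / < 10% LEC filters,
array-detectable genes) is scored per patient with the same rank z-score.

**Synthetic data with ground truth** (`lnstroma.simulate`) — seeded
negative-binomial count simulator (per-gene mean and dispersion, log-normal
library sizes, beta-distributed mitochondrial fractions) with subcluster
marker programs, planted cohort/site effect genes, light-chain-restricted
clones, spiked ligand–receptor couplings, and survival cohorts with
log-linear hazards.  Every planted effect is returned as machine-readable
ground truth.

## Worked example

`examples/03_call_malignant_bcells.py` simulates three B-cell clusters — a
lambda-restricted clone, a kappa-restricted clone and a polyclonal reactive
cluster — and calls each by light-chain restriction:

```
 cluster  n_cells  n_lambda  n_kappa     ratio             call  low_confidence
 clone_A      300       285       18 15.833333 malignant_lambda           False
 clone_B      300        15      286  0.052448  malignant_kappa           False
reactive      300       124      178  0.696629    non_malignant           False
```

The clones' expressing-cell ratios (15.8 and 0.05) fall far outside the
polyclonal band (0.25–2.0), while the reactive cluster sits at 0.70, near the
60:40 κ:λ background.  `examples/06_prognostic_screen.py` runs the survival
screen on a 300-patient synthetic cohort where `LOX` carries a true hazard
ratio of 2 per log-expression unit and `PTGIS` carries none:

```
LOX: maxstat cutpoint 7.80 (76 high / 224 low)
  log-rank chi2 = 72.0, p = 2.14e-17
  outcome screen: high-expression in 59/144 unfavourable vs 4/66 favourable
  patients (one-sided p = 3.63e-08) -> prognostic: True
PTGIS: ... (one-sided p = 0.231) -> prognostic: False
```

The planted marker is flagged and the null gene is not; the subsequent
multivariate Cox fit retains the dichotomized `LOX` indicator alongside IPI.
The other examples cover simulation and I/O (`01`), QC (`02`), differential
expression with confounder subtraction (`04`) and the full ligand–receptor
screen (`05`); each prints the numbers it computes and a line on what they
mean.

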
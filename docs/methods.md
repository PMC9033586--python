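# Methods

This note documents the statistical models, the parameter choices and the
numerical decisions behind `lnstroma`, and what its synthetic-data validation
does and does not establish about real data.

## Synthetic count model

Counts are negative-binomial: for cell *c* and gene *g*,
`X_cg ~ NB(mean = s_c * m_g * f_cg, size = r)` with per-gene baseline means
`m_g = exp(N(μ₀, σ₀²))` (defaults μ₀ = 0, σ₀ = 1, i.e. a long-tailed mean
distribution around ~1 UMI/cell), a common size parameter `r = 2` (variance
`μ + μ²/r`, overdispersion typical of UMI data), and a log-normal library-size
factor `s_c = exp(N(0, 0.3²))`.  All planted structure enters through the
multiplicative factor `f_cg`:

* **marker programs** — each subcluster owns a block of marker genes boosted
  2³-fold, giving clusters a recognizable identity;
* **cohort effects** — applied only in FL cells of the designated subcluster
  (a planted log2 effect of 2 is a 4-fold mean shift);
* **site effects** — applied only in mesenteric-LN cells, creating the
  anatomical confounder the DE stage must subtract;
* **ligand–receptor couplings** — ligand boosted in FL cells of the sender
  subcluster (which simultaneously makes it FL-upregulated there, as the
  integration filter requires), receptor boosted in malignant B cells.

Effects are applied to the NB mean before library-size scaling.
Mitochondrial fractions are Beta(2, 38) (mean 5%), so the QC rule has
something to act on.  B-cell light chains: each cell carries one chain
(restricted in a clone; kappa with probability 0.6 in the polyclonal
background, the typical human ratio); the carried chain gene has NB mean 30,
the other 0.01 — on the log-CP10K scale this puts carried chains far above
and non-carried chains far below the IGLC2 > 1 / IGKC > 2 thresholds, with
realistic dropout on both sides.

Survival cohorts store Gaussian log-scale expression intensities
`x ~ N(7, 1)` (log-normal on the natural scale, as microarray intensities
are).  Event times are exponential with hazard
`λ = λ₀ exp(Σ_g β_g (x_g − 7) + 0.3 · IPI)`, λ₀ = ln2/8 yr⁻¹ (8-year median
baseline survival, in the range of indolent lymphoma cohorts), IPI ordinal
0–3.  Censoring is independent exponential with rate
`λ₀ · c/(1 − c)`, which censors roughly a fraction *c* of patients at
baseline hazard (less when planted effects raise the event rate).

What the generator does **not** emulate: ambient RNA, doublet transcriptomes,
batch chemistry, the real atlas's ~30-subcluster marker biology, correlated
gene programs, or non-proportional hazards.  Passing recovery tests therefore
demonstrates correctness of the statistical machinery under its stated
assumptions, not robustness to those real-data artefacts.

## Quality control

Filtering order is fixed and reported: (1) genes detected in fewer than
`min_cells = 3` cells; (2) cells expressing fewer than `min_genes = 200`
genes; (3) doublet rule, detected genes > 3x median; (4) mitochondrial rule,
load > 2x median.  Medians are computed on the input to the doublet/mito
step.  All four inequalities are strict, so ties at a threshold are retained.
"Mitochondrial load" defaults to the UMI fraction (the standard QC metric);
a distinct-mitochondrial-gene-count mode is available
(`mito_mode="ngenes"`) because the phrase "number of mitochondrial genes" is
ambiguous in the field.  A zero median mitochondrial load skips the rule with
a warning rather than dividing by zero.  Ribosomal-gene removal
(`^RPL|^RPS`) is available but off by default — synthetic universes have no
ribosomal genes.  Normalization is `log1p(CP10K)`; every downstream threshold
("> 1", "> 2", "> 20% expressing") is defined on this scale.  Cells with zero
totals produce all-zero rows plus a warning.

## Light-chain restriction calling

The call uses strict thresholds and the asymmetric ratio bounds
(> 2.0 lambda, < 0.25 kappa; the asymmetry mirrors the 60:40 polyclonal
background).  Boundary policy where convention is silent: `n_κ = 0` with
`n_λ > 0` yields ratio ∞ → lambda-restricted; both zero yields
`indeterminate` rather than a guess.  Clusters under 10 cells are called but
flagged low-confidence.  The signature score is a rank z-score: per profile,
`(mean rank of set genes − mean rank of all genes) / SD of ranks`, ascending
ranks with ties averaged.  It is invariant to monotone rescaling, zero for
the whole-universe set, and is a deliberate light-weight approximation of
kernel-based gene-set variation scoring — adequate for its corroborative
role, not a reimplementation of that method.

## Differential expression

Pre-filters: expressed in ≥ 20% of cells in at least one group, and
|ln fold-change| ≥ 0.25, where
`log_fc = ln(mean(expm1 x₁) + 1e−9) − ln(mean(expm1 x₂) + 1e−9)` (the
pseudocount only guards all-zero groups).  Tests:

* **Rank-sum** — exact enumeration over all `C(n₁+n₂, n₁)` rank assignments
  (tie-aware, two-sided as twice the smaller tail, capped at 1) when both
  groups have ≤ 8 cells; otherwise the tie-corrected continuity-corrected
  normal approximation.  Identical pooled values return p = 1.
* **Hurdle** — detection modelled by logistic regression on group + the
  standardized per-cell detection rate (fraction of genes detected, computed
  over the full gene universe); positive values by a Gaussian linear model on
  the same design.  The group term's likelihood-ratio χ² values are summed
  (df summed likewise).  Complete separation in the logistic part falls back
  to a Haldane-corrected (+0.5) 2×2 likelihood-ratio statistic with a
  warning; a component with fewer than 2 positive cells per group is skipped
  (its df is not counted).

**Bonferroni family.** The default family is *all* genes in the matrix, not
just those passing the pre-filters.  The pre-filter is data-dependent
(it preferentially admits genes that fluctuated), so correcting only over
tested genes is anti-conservative — null simulations showed a per-comparison
false-consensus rate near 20% with the tested-only family versus the intended
near-zero rate with the full family, which also matches the behaviour
documented by mainstream single-cell toolkits.  The tested-only family
remains available (`bonferroni_family="tested"`).

Consensus requires both adjusted p-values < 0.05.  Site-axis comparisons are
restricted to control (MFLN) samples by default so site differences are
profiled free of disease effects.  Confounder subtraction removes any
consensus site DEG regardless of direction (conservative; a
direction-matched mode exists).  Subtraction never adds genes and keeps the
removed genes as provenance.

## Ligand–receptor screening

Scores are products of subpopulation means on the linear CP10K scale
(`expm1` of the normalized values), so a score is a product of average
expression levels; a log-scale option exists.  The > 20% expression filter is
applied per sample (matching per-sample testing).  The permutation null
shuffles the cluster labels of all input cells; one shared set of shuffles
serves every pair in a sample (cheaper, and equivalent under the null).
Internally a shuffle is realised by re-dealing cells into clusters of fixed
sizes via a cumulative-sum slice, which is algebraically identical to
permuting labels.  p-values are `#{null ≥ obs}/n_perm` clamped below at
`1/n_perm` so Fisher's method is always defined.  An exhaustive-enumeration
mode exists for small inputs and is tested against brute force.

Integration: keep (pair, sender) significant in strictly more than half of
samples; require the ligand upregulated in the sender subcluster
(log FC > 0, adjusted rank-sum p < 0.05) in disease vs control; Fisher
combination over per-sample p-values (k = 1 candidates are combined
trivially and flagged); Benjamini–Hochberg across retained candidates;
normalized score = min-max over senders within each pair (a single sender
normalizes to 1.0).  Min-max was chosen over z-scaling because it yields the
dot-plot-ready [0, 1] range; z-scaling is available behind a flag.

**Calibration caveat.** Permutation p-values are uniform under an
*exchangeable* null.  Cluster marker programs change library composition and
hence CP10K values of all genes, so even "unrelated" genes are informative
about labels in marker-bearing data — the test correctly detects this as
cluster structure.  The calibration study therefore uses marker-free
configurations; on real data, permutation p-values measure
cluster-specificity of the score, not a composition-free null.

## Prognostic screen

The maximally selected rank statistic is an exhaustive search: every unique
expression value whose induced split keeps at least `minprop = 0.1` (the
conventional default) of patients on each side is evaluated with the
standardized log-rank statistic `|O − E|/√V` (hypergeometric variance); ties
take the smallest maximizing cutpoint.  The implementation *is* the search
and is verified against an independent re-implementation on small cohorts.
A `min_patients = 20` guard protects against unstable cutpoints and can be
lowered explicitly for toy inputs.  Note the maximizing cutpoint's log-rank
p-value is selection-biased; the screen therefore never uses it for
inference, only for dichotomization.

Outcome groups: favourable = alive 10 years after diagnosis (death at
≥ 10 years also qualifies — the patient was alive at the landmark);
unfavourable = death before 5 years (strict); everyone else intermediate.
The partition is exhaustive and mutually exclusive.  The proportion
comparison is a one-sided Fisher exact test (higher high-expression
proportion among unfavourable patients), α = 0.05; a two-sided mode is
available since the convention is not universal.  Cox models enter genes as
maxstat-dichotomized indicators plus IPI as an ordinal numeric covariate; no
multiplicity correction is applied across genes at the multivariate step
(candidates are few by construction after the specificity and outcome
screens).  Non-convergence raises an explicit error.  Times are years
internally; a reader flag converts months.

## Problem sizes used in validation

Calibration and recovery studies run at desk scale, chosen to make the
targeted property measurable with comfortable margin: ~2,000 permutation
pair-tests (50 marker-free datasets x 40 scored pairs, 1,000 permutations
each); 40 null DEG datasets at ~150 cells/group x 300 genes; 200 null
survival cohorts of 80 patients; 100 clone-calling datasets (200
cells/cluster, restriction fraction 0.8); one DEG-recovery dataset at 300
cells/group with five planted 4-fold cohort genes and three site-confounded
decoys; 20 interaction studies (3 planted couplings among 50 decoys, 9
disease + 4 control samples); survival recovery at n = 500 (and bias checks
at n = 2,000).  `scripts/acceptance.py` recomputes all of these from scratch
for any seed.

## Known limitations

* The hurdle test is a two-part LRT with a CDR covariate — the same modelling
  idea as the established single-cell hurdle framework, but not numerically
  identical to any external package; it is validated by calibration and
  power properties.
* Receptor complexes are out of scope: pairs are single gene x single gene.
* The signature score is a rank approximation, not kernel-density gene-set
  scoring.
* Clustering, integration and trajectory inference are consumed as labels,
  never computed.
* Exponential event/censoring times satisfy proportional hazards by
  construction; the Cox recovery results say nothing about misspecified
  hazards.
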
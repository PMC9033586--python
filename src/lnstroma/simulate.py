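"""Seeded synthetic data generators with planted ground truth.

Every downstream stage of the toolkit (QC, clonality calling, differential
expression, ligand–receptor screening, prognostic screening) is exercised on
data produced here.  The generators emit the statistical structure those
stages assume:

* negative-binomial UMI counts with per-gene baseline means, per-gene
  dispersion and a log-normal per-cell library-size factor — the standard
  scRNA-seq noise model;
* subcluster-specific marker programs (multiplicative mean shifts);
* disease-cohort (FL vs MFLN) effect genes applied only in FL cells of
  designated subclusters, and anatomical-site (mLN vs pLN) effect genes
  applied only in mLN cells — the confounder axis the differential-expression
  stage must subtract;
* clonal B-cell populations with immunoglobulin light-chain restriction
  (IGKC / IGLC2) on a polyclonal background with a 60:40 kappa:lambda ratio;
* spiked ligand–receptor couplings between a stromal sender subcluster and
  malignant B cells;
* survival cohorts whose hazard is log-linear in designated gene expressions
  and in an IPI-like clinical covariate.

All generators are deterministic given their seed: the same configuration and
seed yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from anndata import AnnData

COHORTS = ("MFLN", "FL")
SITES = ("mLN", "pLN")
COMPONENTS = ("BEC", "LEC", "NESC", "HAEM", "BCELL")

#: default stromal subcluster layout: name -> major non-haematopoietic component
DEFAULT_SUBCLUSTERS: Mapping[str, str] = {
    "BEC_art": "BEC",
    "BEC_HEV": "BEC",
    "LEC_ceil": "LEC",
    "LEC_floor": "LEC",
    "TRC": "NESC",
    "FDC": "NESC",
}


@dataclass(frozen=True)
class EffectSpec:
    """A planted differential-expression effect.

    ``axis`` is ``"cohort"`` (applied multiplicatively in FL cells of
    ``subcluster``) or ``"site"`` (applied in mLN cells of ``subcluster``).
    ``log2_fc`` is the log2 of the multiplicative shift on the NB mean.
    """

    gene: str
    subcluster: str
    log2_fc: float
    axis: str = "cohort"


@dataclass(frozen=True)
class CloneSpec:
    """A planted clonal B-cell population.

    ``clone_fraction`` of the cluster's cells belong to the clone and express
    only the restricted light chain; the remainder are polyclonal.
    """

    cluster: str
    chain: str  # "kappa" | "lambda"
    clone_fraction: float
    n_cells: int = 200


@dataclass(frozen=True)
class InteractionSpec:
    """A planted ligand–receptor coupling.

    The ligand is boosted (x ``2**effect_size``) in FL cells of the sender
    stromal subcluster; the receptor is boosted in malignant B cells.  When
    ``ligand``/``receptor`` are ``None`` the interaction-study generator
    assigns genes from its reserved ligand–receptor gene block.
    """

    ligand: str | None = None
    receptor: str | None = None
    sender: str = "TRC"
    effect_size: float = 2.0


@dataclass(frozen=True)
class SurvivalEffect:
    gene: str
    log_hr: float


@dataclass
class GroundTruth:
    """Record of every effect planted into a simulated dataset."""

    planted_deg: list[EffectSpec] = field(default_factory=list)
    planted_clones: list[CloneSpec] = field(default_factory=list)
    planted_interactions: list[InteractionSpec] = field(default_factory=list)
    survival_effects: list[SurvivalEffect] = field(default_factory=list)

    def frames(self) -> dict[str, pd.DataFrame]:
        return {
            name: pd.DataFrame([dataclasses.asdict(x) for x in getattr(self, name)])
            for name in (
                "planted_deg",
                "planted_clones",
                "planted_interactions",
                "survival_effects",
            )
        }


@dataclass
class SimConfig:
    """Configuration of the count simulator.

    Baseline per-gene NB means are log-normal across genes
    (``exp(N(base_mean_log_mu, base_mean_log_sigma))`` UMI per cell); ``nb_size``
    is the NB size parameter r (variance = mu + mu^2 / r); the per-cell
    library-size factor is ``exp(N(0, libsize_sigma))``; per-cell mitochondrial
    fraction is Beta(``mito_beta_a``, ``mito_beta_b``).
    """

    n_genes: int = 300
    cells_per_subcluster: int = 100
    samples_per_group: int = 2  # per cohort x site
    subclusters: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_SUBCLUSTERS))
    n_marker_genes: int = 5
    marker_log2_fc: float = 3.0
    base_mean_log_mu: float = 0.0
    base_mean_log_sigma: float = 1.0
    nb_size: float = 2.0
    libsize_sigma: float = 0.3
    mito_beta_a: float = 2.0
    mito_beta_b: float = 38.0
    cohort_effects: list[EffectSpec] = field(default_factory=list)
    site_effects: list[EffectSpec] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("cohort_effects", "site_effects"):
            raw[key] = [EffectSpec(**d) for d in raw.get(key, [])]
        return cls(**raw)

    def validate(self) -> None:
        if self.n_genes < 1 or self.cells_per_subcluster < 1 or self.samples_per_group < 1:
            raise ValueError("n_genes, cells_per_subcluster and samples_per_group must be positive")
        if self.cells_per_subcluster < 3:
            raise ValueError("fewer than 3 cells per subcluster")
        if self.nb_size <= 0:
            raise ValueError("negative-binomial size (inverse dispersion) must be > 0")
        if self.base_mean_log_sigma < 0 or self.libsize_sigma < 0:
            raise ValueError("scale parameters must be non-negative")
        per_component: dict[str, int] = {}
        for name, comp in self.subclusters.items():
            if comp not in COMPONENTS:
                raise ValueError(f"unknown component {comp!r} for subcluster {name!r}")
            per_component[comp] = per_component.get(comp, 0) + 1
        if any(n < 2 for n in per_component.values()):
            raise ValueError("each represented component needs >= 2 subclusters")


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, size_r: float) -> np.ndarray:
    """Negative-binomial counts with mean mu and size r (mu may contain zeros)."""
    if np.any(mu < 0):
        raise ValueError("negative NB mean")
    p = size_r / (size_r + mu)
    return rng.negative_binomial(size_r, p)


def _baseline(rng: np.random.Generator, config: SimConfig) -> tuple[list[str], np.ndarray]:
    genes = _gene_names(config.n_genes)
    base_mean = np.exp(
        rng.normal(config.base_mean_log_mu, config.base_mean_log_sigma, size=config.n_genes)
    )
    return genes, base_mean


def generate_nhc_dataset(
    config: SimConfig,
) -> tuple[AnnData, pd.DataFrame, GroundTruth]:
    """Simulate the non-haematopoietic (stromal) compartment of the atlas.

    Returns a counts AnnData (cells x genes, UMI counts in ``.X``), a cell
    metadata frame (also stored as ``adata.obs``) and the planted ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, base_mean = _baseline(rng, config)
    gene_index = {g: i for i, g in enumerate(genes)}

    sub_names = list(config.subclusters)
    # marker program: subcluster k owns a block of genes at the front of the universe
    marker_mult = np.ones((len(sub_names), config.n_genes))
    for k, _ in enumerate(sub_names):
        lo = k * config.n_marker_genes
        hi = min(lo + config.n_marker_genes, config.n_genes)
        marker_mult[k, lo:hi] = 2.0**config.marker_log2_fc

    for eff in config.cohort_effects + config.site_effects:
        if eff.gene not in gene_index:
            raise ValueError(f"planted effect gene {eff.gene!r} outside the gene universe")
        if eff.subcluster not in config.subclusters:
            raise ValueError(f"planted effect subcluster {eff.subcluster!r} not simulated")
        if not np.isfinite(eff.log2_fc):
            raise ValueError("effect sizes must be finite")

    blocks: list[np.ndarray] = []
    obs_rows: list[dict] = []
    cell_counter = 0
    for cohort in COHORTS:
        for site in SITES:
            for s in range(config.samples_per_group):
                sample_id = f"{cohort}_{site}_{s + 1}"
                for k, sub in enumerate(sub_names):
                    mean = base_mean * marker_mult[k]
                    mult = np.ones(config.n_genes)
                    if cohort == "FL":
                        for eff in config.cohort_effects:
                            if eff.subcluster == sub:
                                mult[gene_index[eff.gene]] *= 2.0**eff.log2_fc
                    if site == "mLN":
                        for eff in config.site_effects:
                            if eff.subcluster == sub:
                                mult[gene_index[eff.gene]] *= 2.0**eff.log2_fc
                    mean = mean * mult
                    n = config.cells_per_subcluster
                    lib = np.exp(rng.normal(0.0, config.libsize_sigma, size=n))
                    mu = lib[:, None] * mean[None, :]
                    blocks.append(_nb_draw(rng, mu, config.nb_size))
                    mito = rng.beta(config.mito_beta_a, config.mito_beta_b, size=n)
                    for i in range(n):
                        obs_rows.append(
                            {
                                "cell_id": f"cell{cell_counter + i:06d}",
                                "sample_id": sample_id,
                                "cohort": cohort,
                                "site": site,
                                "component": config.subclusters[sub],
                                "subcluster": sub,
                                "mito_fraction": mito[i],
                            }
                        )
                    cell_counter += n

    counts = np.vstack(blocks)
    obs = pd.DataFrame(obs_rows).set_index("cell_id", drop=False)
    obs.index.name = None
    adata = AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name=None)),
    )
    truth = GroundTruth(planted_deg=list(config.cohort_effects) + list(config.site_effects))
    return adata, obs, truth


def generate_bcell_dataset(
    config: SimConfig,
    clone_specs: Sequence[CloneSpec],
    *,
    kappa_prob: float = 0.6,
    chain_high_mean: float = 30.0,
    chain_off_mean: float = 0.01,
    sample_id: str = "FL_1",
) -> tuple[AnnData, pd.DataFrame, GroundTruth]:
    """Simulate B-cell clusters with optional planted light-chain-restricted clones.

    Each cell carries one light chain: in a clone the restricted chain, in the
    polyclonal background kappa with probability ``kappa_prob``.  The carried
    chain gene (IGKC for kappa, IGLC2 for lambda) has NB mean
    ``chain_high_mean``; the other chain has mean ``chain_off_mean``.  CD79A is
    expressed in every cell.  With ``clone_specs`` empty a single polyclonal
    cluster is generated.
    """
    config.validate()
    specs = list(clone_specs)
    for cs in specs:
        if not 0.0 <= cs.clone_fraction <= 1.0:
            raise ValueError(f"clone fraction {cs.clone_fraction} outside [0, 1]")
        if cs.chain not in ("kappa", "lambda"):
            raise ValueError(f"unknown chain {cs.chain!r}")
        if cs.n_cells < 3:
            raise ValueError("fewer than 3 cells in a cluster")
    if not specs:
        specs = [CloneSpec("B_poly", "kappa", 0.0, n_cells=config.cells_per_subcluster)]
        truth_clones: list[CloneSpec] = []
    else:
        truth_clones = [cs for cs in specs if cs.clone_fraction > 0]

    rng = np.random.default_rng(config.seed)
    bg_genes, bg_mean = _baseline(rng, config)
    genes = ["CD79A", "IGKC", "IGLC2"] + bg_genes

    blocks = []
    obs_rows = []
    counter = 0
    for cs in specs:
        n = cs.n_cells
        n_clone = int(round(cs.clone_fraction * n))
        chains = np.empty(n, dtype=object)
        chains[:n_clone] = cs.chain
        poly = rng.random(n - n_clone) < kappa_prob
        chains[n_clone:] = np.where(poly, "kappa", "lambda")

        mean = np.empty((n, len(genes)))
        mean[:, 3:] = bg_mean[None, :]
        mean[:, 0] = 10.0  # CD79A, pan-B marker
        is_kappa = chains == "kappa"
        mean[:, 1] = np.where(is_kappa, chain_high_mean, chain_off_mean)  # IGKC
        mean[:, 2] = np.where(is_kappa, chain_off_mean, chain_high_mean)  # IGLC2
        lib = np.exp(rng.normal(0.0, config.libsize_sigma, size=n))
        blocks.append(_nb_draw(rng, lib[:, None] * mean, config.nb_size))
        mito = rng.beta(config.mito_beta_a, config.mito_beta_b, size=n)
        for i in range(n):
            obs_rows.append(
                {
                    "cell_id": f"bcell{counter + i:06d}",
                    "sample_id": sample_id,
                    "cohort": "FL",
                    "site": "pLN",
                    "component": "BCELL",
                    "subcluster": cs.cluster,
                    "mito_fraction": mito[i],
                    "true_chain": chains[i],
                }
            )
        counter += n

    counts = np.vstack(blocks)
    obs = pd.DataFrame(obs_rows).set_index("cell_id", drop=False)
    obs.index.name = None
    adata = AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes)),
    )
    return adata, obs, GroundTruth(planted_clones=truth_clones)


def generate_lr_reference(
    n_pairs: int,
    genes: Sequence[str],
    planted: Sequence[InteractionSpec] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """A synthetic ligand–receptor reference table (columns ``ligand,receptor``).

    Stands in for a curated receptor–ligand database: ``n_pairs`` unique pairs
    over disjoint genes from the simulated universe, always containing every
    planted coupling.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rows = [(p.ligand, p.receptor) for p in planted]
    if len(set(rows)) != len(rows):
        raise ValueError("duplicate planted ligand-receptor pair")
    if len(rows) > n_pairs:
        raise ValueError("more planted pairs than n_pairs")
    used = {g for pair in rows for g in pair}
    pool = [g for g in genes if g not in used]
    n_decoys = n_pairs - len(rows)
    if 2 * n_decoys > len(pool):
        raise ValueError("n_pairs exceeds the available gene universe")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=2 * n_decoys, replace=False)
    for i in range(n_decoys):
        rows.append((pool[chosen[2 * i]], pool[chosen[2 * i + 1]]))
    return pd.DataFrame(rows, columns=["ligand", "receptor"])


@dataclass
class InteractionStudy:
    """A multi-sample dataset for the ligand–receptor screening stage.

    ``samples`` maps each FL sample id to a counts AnnData holding that
    sample's stromal subclusters plus its malignant B-cell cluster
    (``B_malignant``).  ``stroma`` holds the stromal cells of all samples from
    both cohorts (for the FL-vs-MFLN upregulation filter).
    """

    samples: dict[str, AnnData]
    stroma: AnnData
    lr_table: pd.DataFrame
    truth: GroundTruth


def generate_interaction_dataset(
    config: SimConfig,
    interactions: Sequence[InteractionSpec] = (),
    *,
    n_fl_samples: int = 9,
    n_mfln_samples: int = 4,
    n_pairs: int = 53,
    bcells_per_sample: int = 60,
    lr_gene_mean: float = 1.0,
    receptor_boost_log2: float = 2.0,
) -> InteractionStudy:
    """Simulate the full ligand–receptor study layout.

    Stromal subclusters are generated for ``n_fl_samples`` FL and
    ``n_mfln_samples`` MFLN samples.  Genes used in the ligand–receptor table
    get a common baseline NB mean (``lr_gene_mean``) so the >20%-expressing
    filter is satisfiable, and carry no subcluster marker structure, which
    makes cluster labels exchangeable for unplanted pairs.  Each planted
    coupling boosts its ligand by ``2**effect_size`` in FL cells of the sender
    subcluster (so it is also FL-upregulated there) and its receptor by
    ``2**receptor_boost_log2`` in the malignant B cells of every FL sample.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, base_mean = _baseline(rng, config)
    sub_names = list(config.subclusters)

    # reserve genes for the LR table from the back of the universe (no markers)
    n_lr_genes = 2 * n_pairs
    n_marker_total = len(sub_names) * config.n_marker_genes
    if n_marker_total + n_lr_genes > config.n_genes:
        raise ValueError("gene universe too small for markers plus LR pairs")
    lr_genes = genes[-n_lr_genes:]
    base_mean = base_mean.copy()
    base_mean[-n_lr_genes:] = lr_gene_mean

    for spec in interactions:
        if spec.sender not in config.subclusters:
            raise ValueError(f"sender subcluster {spec.sender!r} not simulated")
    planted = [
        dataclasses.replace(spec, ligand=lr_genes[2 * i], receptor=lr_genes[2 * i + 1])
        if spec.ligand is None
        else spec
        for i, spec in enumerate(interactions)
    ]
    for spec in planted:
        if spec.ligand not in genes or spec.receptor not in genes:
            raise ValueError("planted interaction genes outside the gene universe")
    lr_table = generate_lr_reference(n_pairs, lr_genes, planted, seed=config.seed + 1)

    gene_index = {g: i for i, g in enumerate(genes)}
    marker_mult = np.ones((len(sub_names), config.n_genes))
    for k in range(len(sub_names)):
        lo = k * config.n_marker_genes
        marker_mult[k, lo : lo + config.n_marker_genes] = 2.0**config.marker_log2_fc

    samples: dict[str, AnnData] = {}
    stroma_blocks: list[np.ndarray] = []
    stroma_obs: list[dict] = []
    counter = 0

    def stromal_cells(sample_id: str, cohort: str, site: str) -> tuple[np.ndarray, pd.DataFrame]:
        nonlocal counter
        rows = []
        block = []
        for k, sub in enumerate(sub_names):
            mean = base_mean * marker_mult[k]
            if cohort == "FL":
                mult = np.ones(config.n_genes)
                for spec in planted:
                    if spec.sender == sub:
                        mult[gene_index[spec.ligand]] *= 2.0**spec.effect_size
                mean = mean * mult
            n = config.cells_per_subcluster
            lib = np.exp(rng.normal(0.0, config.libsize_sigma, size=n))
            block.append(_nb_draw(rng, lib[:, None] * mean, config.nb_size))
            for i in range(n):
                rows.append(
                    {
                        "cell_id": f"cell{counter + i:06d}",
                        "sample_id": sample_id,
                        "cohort": cohort,
                        "site": site,
                        "component": config.subclusters[sub],
                        "subcluster": sub,
                        "mito_fraction": 0.05,
                    }
                )
            counter += n
        return np.vstack(block), pd.DataFrame(rows)

    var = pd.DataFrame(index=pd.Index(genes))
    for s in range(n_fl_samples):
        sample_id = f"FL_{s + 1}"
        site = SITES[s % 2]
        scounts, sobs = stromal_cells(sample_id, "FL", site)
        # malignant B cells of this sample
        b_mean = base_mean.copy()
        for spec in planted:
            b_mean[gene_index[spec.receptor]] *= 2.0**receptor_boost_log2
        lib = np.exp(rng.normal(0.0, config.libsize_sigma, size=bcells_per_sample))
        b_counts = _nb_draw(rng, lib[:, None] * b_mean[None, :], config.nb_size)
        b_obs = pd.DataFrame(
            {
                "cell_id": [f"cell{counter + i:06d}" for i in range(bcells_per_sample)],
                "sample_id": sample_id,
                "cohort": "FL",
                "site": site,
                "component": "BCELL",
                "subcluster": "B_malignant",
                "mito_fraction": 0.05,
            }
        )
        counter += bcells_per_sample
        obs = pd.concat([sobs, b_obs], ignore_index=True).set_index("cell_id", drop=False)
        obs.index.name = None
        samples[sample_id] = AnnData(
            X=sp.csr_matrix(np.vstack([scounts, b_counts]).astype(np.int64)),
            obs=obs,
            var=var.copy(),
        )
        stroma_blocks.append(scounts)
        stroma_obs.extend(sobs.to_dict("records"))

    for s in range(n_mfln_samples):
        sample_id = f"MFLN_{s + 1}"
        scounts, sobs = stromal_cells(sample_id, "MFLN", SITES[s % 2])
        stroma_blocks.append(scounts)
        stroma_obs.extend(sobs.to_dict("records"))

    sobs_all = pd.DataFrame(stroma_obs).set_index("cell_id", drop=False)
    sobs_all.index.name = None
    stroma = AnnData(
        X=sp.csr_matrix(np.vstack(stroma_blocks).astype(np.int64)),
        obs=sobs_all,
        var=var.copy(),
    )
    truth = GroundTruth(planted_interactions=planted)
    return InteractionStudy(samples=samples, stroma=stroma, lr_table=lr_table, truth=truth)


def generate_survival_cohort(
    n_patients: int,
    survival_effects: Sequence[SurvivalEffect] = (),
    censor_rate: float = 0.3,
    seed: int = 0,
    *,
    n_noise_genes: int = 5,
    baseline_median_years: float = 8.0,
    expr_loc: float = 7.0,
    ipi_log_hr: float = 0.3,
) -> pd.DataFrame:
    """Simulate a bulk expression + overall-survival cohort.

    Stored expression values are Gaussian log-scale intensities
    (``N(expr_loc, 1)``; the natural-scale expression is log-normal).  Event
    times are exponential with a log-hazard linear in the centred expression of
    each effect gene (slope = its log hazard ratio) and in an ordinal IPI-like
    covariate (slope ``ipi_log_hr`` per category).  Censoring is independent
    exponential with rate set so that roughly ``censor_rate`` of baseline
    patients are censored.
    """
    if n_patients < 20:
        raise ValueError("need at least 20 patients")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    effects = list(survival_effects)
    for e in effects:
        if not np.isfinite(e.log_hr):
            raise ValueError("log hazard ratios must be finite")

    rng = np.random.default_rng(seed)
    gene_names = [e.gene for e in effects] + [f"N{i:02d}" for i in range(1, n_noise_genes + 1)]
    if len(set(gene_names)) != len(gene_names):
        raise ValueError("duplicate gene names in the survival cohort")
    expr = rng.normal(expr_loc, 1.0, size=(n_patients, len(gene_names)))
    ipi = rng.choice([0, 1, 2, 3], size=n_patients, p=[0.3, 0.3, 0.25, 0.15])

    log_hr = np.zeros(n_patients)
    for j, e in enumerate(effects):
        log_hr += e.log_hr * (expr[:, j] - expr_loc)
    log_hr += ipi_log_hr * ipi
    lam0 = np.log(2.0) / baseline_median_years
    event_t = rng.exponential(1.0 / (lam0 * np.exp(log_hr)))
    if censor_rate > 0:
        lam_c = lam0 * censor_rate / (1.0 - censor_rate)
        censor_t = rng.exponential(1.0 / lam_c, size=n_patients)
    else:
        censor_t = np.full(n_patients, np.inf)
    time = np.minimum(event_t, censor_t)
    event = event_t <= censor_t

    cohort = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n_patients)],
            "time": time,
            "event": event.astype(int),
            "ipi": ipi,
        }
    )
    for j, g in enumerate(gene_names):
        cohort[g] = expr[:, j]
    return cohort
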
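"""Prognostic screen: specificity filters, maxstat oracle, KM/log-rank, Cox."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

import lnstroma as ln
from lnstroma.simulate import SurvivalEffect
from tests.conftest import make_adata


def _deg_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "subcluster", "log_fc", "padj_rank", "consensus"])


def _haem_matrix(expr_frac_by_gene, n_cells=2000):
    genes = list(expr_frac_by_gene)
    X = np.zeros((n_cells, len(genes)))
    for j, g in enumerate(genes):
        k = int(round(expr_frac_by_gene[g] * n_cells))
        X[:k, j] = 1.5
    return make_adata(X, genes=genes, counts=False)


class TestStromaSpecificCandidates:
    def test_threshold_rules(self):
        degs = _deg_frame(
            [
                ("A", "TRC", 0.6, 0.001, True),   # specific -> kept
                ("B", "TRC", 0.6, 0.001, True),   # 5% haem -> dropped
                ("C", "TRC", 0.4, 0.001, True),   # log_fc <= 0.5 -> dropped
                ("D", "TRC", 0.5, 0.001, True),   # exactly 0.5: strict > -> dropped
            ]
        )
        haem = _haem_matrix({"A": 0.0, "B": 0.05, "C": 0.0, "D": 0.0})
        assert ln.stroma_specific_candidates(degs, haem) == ["A"]

    def test_absent_gene_counts_as_silent(self):
        degs = _deg_frame([("ZZZ", "TRC", 0.9, 0.001, True)])
        haem = _haem_matrix({"A": 0.0})
        with pytest.warns(UserWarning, match="absent"):
            assert ln.stroma_specific_candidates(degs, haem) == ["ZZZ"]

    def test_haem_boundary_strictly_below(self):
        # exactly 0.1% expressing fails the "< 0.1%" rule
        degs = _deg_frame([("A", "TRC", 0.9, 0.001, True)])
        haem = _haem_matrix({"A": 0.001}, n_cells=2000)
        assert ln.stroma_specific_candidates(degs, haem) == []


def brute_force_maxstat(cohort, gene, minprop):
    """Independent exhaustive search using lifelines' log-rank statistic."""
    x = cohort[gene].to_numpy()
    n = len(cohort)
    best = None
    for c in np.unique(x)[:-1]:
        high = x > c
        if not (minprop * n <= high.sum() <= (1 - minprop) * n):
            continue
        res = logrank_test(
            cohort.time[high], cohort.time[~high],
            event_observed_A=cohort.event[high], event_observed_B=cohort.event[~high],
        )
        stat = np.sqrt(res.test_statistic)
        if best is None or stat > best[1] + 1e-12:
            best = (c, stat)
    return best


class TestMaxstat:
    def test_separable_case_cut_between_blocks(self):
        # low expression -> early deaths; high expression -> long survivors
        n = 24
        cohort = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "time": [1.0] * 12 + [20.0] * 12,
                "event": [1] * 12 + [0] * 12,
                "ipi": 1,
                "g": list(np.linspace(0, 1, 12)) + list(np.linspace(5, 6, 12)),
            }
        )
        cut = ln.maxstat_cutpoint(cohort, "g")
        assert 1.0 <= cut.cutpoint < 5.0
        assert cut.n_low == 12 and cut.n_high == 12

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_small_cohorts(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(8, 13)
        cohort = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "time": rng.exponential(5, n) + 0.1,
                "event": rng.integers(0, 2, n) | 1,  # ensure events exist
                "ipi": 1,
                "g": rng.normal(size=n),
            }
        )
        cut = ln.maxstat_cutpoint(cohort, "g", minprop=0.1, min_patients=5)
        oracle_c, oracle_stat = brute_force_maxstat(cohort, "g", 0.1)
        assert cut.cutpoint == pytest.approx(oracle_c)
        assert cut.statistic == pytest.approx(oracle_stat, rel=1e-9)

    def test_constant_expression_errors(self):
        cohort = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(25)],
                "time": np.arange(25) + 1.0,
                "event": 1,
                "ipi": 1,
                "g": 3.0,
            }
        )
        with pytest.raises(ValueError, match="admissible"):
            ln.maxstat_cutpoint(cohort, "g")

    def test_monotone_transform_invariance(self):
        cohort = ln.generate_survival_cohort(60, [SurvivalEffect("G", 0.7)], seed=2)
        cut1 = ln.maxstat_cutpoint(cohort, "G")
        transformed = cohort.copy()
        transformed["G"] = np.exp(transformed["G"] / 2)
        cut2 = ln.maxstat_cutpoint(transformed, "G")
        assert cut2.statistic == pytest.approx(cut1.statistic, rel=1e-9)
        assert (cut1.n_low, cut1.n_high) == (cut2.n_low, cut2.n_high)


class TestKMLogrank:
    def test_identical_groups_null(self):
        half = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(10)],
                "time": np.arange(10) + 1.0,
                "event": [1, 0] * 5,
                "ipi": 1,
            }
        )
        other = half.copy()
        other["patient_id"] = [f"q{i}" for i in range(10)]
        cohort = pd.concat([half, other], ignore_index=True)
        chi2, p, curves = ln.km_logrank(cohort, np.array(["A"] * 10 + ["B"] * 10))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_textbook_hand_computation(self):
        # A: deaths at 1 and 3; B: deaths at 2 and 4.
        # By hand: O_A = 2, E_A = 1/2 + 1/3 + 1/2 = 4/3,
        # V = 1/4 + 2/9 + 1/4 = 13/18, chi2 = (2/3)^2 / (13/18) = 8/13.
        cohort = pd.DataFrame(
            {
                "patient_id": list("abcd"),
                "time": [1.0, 3.0, 2.0, 4.0],
                "event": 1,
                "ipi": 1,
            }
        )
        chi2, p, _ = ln.km_logrank(cohort, np.array(["A", "A", "B", "B"]))
        assert chi2 == pytest.approx(8 / 13, rel=1e-9)

    def test_zero_event_group_warns(self):
        cohort = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(8)],
                "time": np.arange(8) + 1.0,
                "event": [1] * 4 + [0] * 4,
                "ipi": 1,
            }
        )
        with pytest.warns(UserWarning, match="zero events"):
            chi2, p, _ = ln.km_logrank(cohort, np.array(["A"] * 4 + ["B"] * 4))
        assert np.isfinite(chi2)

    def test_power_under_planted_hazard(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cohort = ln.generate_survival_cohort(
                500, [SurvivalEffect("G", np.log(2))], censor_rate=0.3, seed=2000 + seed
            )
            grouping = np.where(cohort.G > cohort.G.median(), "high", "low")
            _, p, _ = ln.km_logrank(cohort, grouping)
            hits += p < 0.001
        assert hits / n_seeds >= 0.95


class TestOutcomeGroups:
    def test_partition_rules(self):
        cohort = pd.DataFrame(
            {
                "patient_id": list("abcdef"),
                "time": [12.0, 4.2, 7.0, 10.0, 5.0, 11.0],
                "event": [0, 1, 1, 1, 1, 1],
                "ipi": 1,
            }
        )
        groups = ln.prognosis.outcome_groups(cohort).tolist()
        # censored 12y -> favourable; death 4.2 -> unfavourable; death 7 ->
        # intermediate; death at exactly 10 -> favourable (alive at 10 years);
        # death at exactly 5 -> intermediate ("within 5 years" is strict);
        # death 11 -> favourable
        assert groups == [
            "favourable", "unfavourable", "intermediate",
            "favourable", "intermediate", "favourable",
        ]

    def test_partition_exhaustive_exclusive(self):
        cohort = ln.generate_survival_cohort(200, [], seed=3)
        groups = ln.prognosis.outcome_groups(cohort)
        assert set(groups) <= {"favourable", "unfavourable", "intermediate"}
        assert len(groups) == 200


def _screen_cohort(n_high_fav, n_fav, n_high_unf, n_unf):
    rows = []
    for i in range(n_fav):
        rows.append({"time": 12.0, "event": 0, "expr": 1.0 if i < n_high_fav else -1.0})
    for i in range(n_unf):
        rows.append({"time": 2.0, "event": 1, "expr": 1.0 if i < n_high_unf else -1.0})
    df = pd.DataFrame(rows)
    df["patient_id"] = [f"p{i}" for i in range(len(df))]
    df["ipi"] = 1
    return df


class TestOutcomeScreen:
    def test_hypergeometric_tail_example(self):
        # 2x2 high/low x favourable/unfavourable = (2,8 / 9,1)
        cohort = _screen_cohort(2, 10, 9, 10)
        res = ln.outcome_group_screen(cohort, "expr", 0.0)
        from scipy.stats import fisher_exact

        _, p_oracle = fisher_exact([[9, 1], [2, 8]], alternative="greater")
        assert res.p == pytest.approx(p_oracle)
        assert res.p < 0.05 and res.prognostic

    def test_equal_proportions_not_flagged(self):
        cohort = _screen_cohort(5, 10, 5, 10)
        res = ln.outcome_group_screen(cohort, "expr", 0.0)
        assert not res.prognostic

    def test_empty_group_insufficient(self):
        cohort = _screen_cohort(2, 10, 0, 0)
        res = ln.outcome_group_screen(cohort, "expr", 0.0)
        assert res.status == "insufficient groups" and not res.prognostic

    def test_raising_cutpoint_only_shrinks_high_group(self):
        cohort = ln.generate_survival_cohort(100, [], seed=5)
        low_cut = ln.outcome_group_screen(cohort, "N01", 6.5)
        high_cut = ln.outcome_group_screen(cohort, "N01", 7.5)
        assert high_cut.n_high_favourable <= low_cut.n_high_favourable
        assert high_cut.n_high_unfavourable <= low_cut.n_high_unfavourable


class TestCox:
    def test_null_coverage(self):
        covered = 0
        n_sims = 40
        for seed in range(n_sims):
            cohort = ln.generate_survival_cohort(150, [], censor_rate=0.2, seed=3000 + seed)
            ind = pd.DataFrame({"flag": (cohort.N01 > cohort.N01.median()).astype(int)})
            fit = ln.cox_adjusted(cohort, ind, ipi=False)
            row = fit[fit.covariate == "flag"].iloc[0]
            covered += row.hr_lower95 <= 1.0 <= row.hr_upper95
        assert covered / n_sims >= 0.85

    def test_hr_recovery_with_ipi_adjustment(self):
        cohort = ln.generate_survival_cohort(
            500, [SurvivalEffect("G", np.log(2))], censor_rate=0.3, seed=7
        )
        fit = ln.cox_adjusted(cohort, cohort[["G"]])
        row = fit[fit.covariate == "G"].iloc[0]
        assert 1.6 < row.hr < 2.5
        ipi_row = fit[fit.covariate == "ipi"].iloc[0]
        assert ipi_row.hr > 1.0  # generated IPI association recovered

    def test_log_hr_bias_small_at_large_n(self):
        biases = []
        for seed in (11, 12, 13):
            cohort = ln.generate_survival_cohort(
                2000, [SurvivalEffect("G", np.log(2))], censor_rate=0.3, seed=seed
            )
            fit = ln.cox_adjusted(cohort, cohort[["G"]], ipi=True)
            beta = np.log(fit[fit.covariate == "G"].hr.iloc[0])
            biases.append(beta - np.log(2))
        assert abs(np.mean(biases)) < 0.05

    def test_constant_covariate_errors(self):
        cohort = ln.generate_survival_cohort(50, [], seed=1)
        with pytest.raises(ValueError, match="variation"):
            ln.cox_adjusted(cohort, pd.DataFrame({"flag": np.zeros(50, int)}))


class TestSignature:
    def test_trc_extraction_rules(self):
        degs = _deg_frame(
            [
                ("A", "TRC", 0.9, 0.001, True),  # specific, on array -> kept
                ("B", "TRC", 0.9, 0.001, True),  # 12% BEC -> dropped
                ("C", "TRC", 0.9, 0.001, True),  # off array -> dropped
                ("D", "TRC", 0.9, 0.001, True),  # exactly 10% BEC -> dropped (< rule)
            ]
        )
        haem = _haem_matrix({"A": 0.0005, "B": 0.0, "C": 0.0, "D": 0.0})
        bec = _haem_matrix({"A": 0.05, "B": 0.12, "C": 0.0, "D": 0.10}, n_cells=100)
        lec = _haem_matrix({"A": 0.05, "B": 0.0, "C": 0.0, "D": 0.0}, n_cells=100)
        out = ln.trc_signature_extract(degs, haem, bec, lec, array_genes=["A", "B", "D"])
        assert out == ["A"]

    def test_empty_result_allowed(self):
        degs = _deg_frame([("B", "TRC", 0.9, 0.001, True)])
        haem = _haem_matrix({"B": 0.5})
        with pytest.warns(UserWarning, match="no genes"):
            out = ln.trc_signature_extract(degs, haem, haem, haem, array_genes=["B"])
        assert out == []

    def test_enrichment_all_genes_identical_score(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(4, 6)), columns=list("ABCDEF"))
        scores = ln.signature_enrichment(expr, list("ABCDEF"))
        assert np.allclose(scores, 0.0)

    def test_toy_manual_ranks(self):
        # 6 genes x 3 patients; signature {A, B}
        expr = pd.DataFrame(
            {
                "A": [6.0, 1.0, 3.0],
                "B": [5.0, 2.0, 3.0],
                "C": [4.0, 3.0, 3.0],
                "D": [3.0, 4.0, 3.0],
                "E": [2.0, 5.0, 1.0],
                "F": [1.0, 6.0, 2.0],
            }
        )
        scores = ln.signature_enrichment(expr, ["A", "B"])
        sd = np.std([1, 2, 3, 4, 5, 6])
        # patient 0: ranks A=6, B=5 -> (5.5 - 3.5)/sd; patient 1 mirrored;
        # patient 2: four-way tie at rank 4.5 for A-D
        sd2 = np.std([4.5, 4.5, 4.5, 4.5, 1, 2])
        expected = [2.0 / sd, -2.0 / sd, (4.5 - 3.5) / sd2]
        assert np.allclose(scores, expected)

    def test_empty_overlap_errors(self):
        expr = pd.DataFrame(np.ones((2, 3)), columns=list("ABC"))
        with pytest.raises(ValueError):
            ln.signature_enrichment(expr, ["X", "Y"])
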
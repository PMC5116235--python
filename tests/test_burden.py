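import math

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from varburden.burden import (
    ALL_CLASSES,
    ContingencyTable,
    MultipleTestingPlan,
    binomial_ci,
    bonferroni_threshold,
    case_excess,
    case_frequency,
    etiological_fraction,
    fisher_exact,
    odds_ratio_ci,
    predicted_pathogenic,
    run_burden,
)
from varburden.frequency import filter_rare
from varburden.synthetic import SyntheticGeneSpec, generate
from varburden.variant_io import CaseVariant, PanelEntry


class TestCaseFrequency:
    def test_most_common_pathogenic_variant_proportion(self):
        # 104 carriers among 6,179 cases is 1.7% at one decimal
        variants = [CaseVariant("HCM", "MYBPC3", "v", "missense_variant", 104)]
        assert round(100 * case_frequency(variants, 6179), 1) == 1.7

    def test_empty_and_simple_sums(self):
        assert case_frequency([], 100) == 0.0
        vs = [
            CaseVariant("D", "G", "a", "missense_variant", 2),
            CaseVariant("D", "G", "b", "missense_variant", 3),
        ]
        assert case_frequency(vs, 100) == 0.05

    def test_capped_at_one_with_warning(self, caplog):
        vs = [CaseVariant("D", "G", "a", "missense_variant", 15)]
        with caplog.at_level("WARNING"):
            assert case_frequency(vs, 10) == 1.0
        assert "capping" in caplog.text

    def test_requires_positive_cohort(self):
        with pytest.raises(ValueError):
            case_frequency([], 0)


class TestCaseExcess:
    @pytest.mark.parametrize(
        "cf,rf,expected", [(0.02, 0.005, 0.015), (0.01, 0.01, 0.0), (0.005, 0.02, -0.015)]
    )
    def test_signed_difference(self, cf, rf, expected):
        assert case_excess(cf, rf) == pytest.approx(expected)


class TestFisher:
    def test_symmetric_table(self):
        assert fisher_exact(ContingencyTable(1, 1, 1, 1)) == 1.0

    def test_extreme_table_enumeration_value(self):
        # 5/5 margins, fully concordant: 2 of the 252 equally-weighted
        # orderings are at least as extreme
        assert fisher_exact(ContingencyTable(5, 0, 0, 5)) == pytest.approx(2 / 252)

    def test_non_integer_cells_rounded(self):
        p_int = fisher_exact(ContingencyTable(5, 95, 10.4, 990.2))
        p_round = fisher_exact(ContingencyTable(5, 95, 10, 990))
        assert p_int == p_round

    def test_degenerate_margin_returns_one(self, caplog):
        with caplog.at_level("WARNING"):
            assert fisher_exact(ContingencyTable(0, 0, 3, 7)) == 1.0

    def test_matches_independent_implementation_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 60, 4))
            if a + b == 0 or c + d == 0:
                continue
            ours = fisher_exact(ContingencyTable(a, b, c, d))
            theirs = scipy_fisher([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_exhaustive_small_margin_grid_matches_exact_enumeration(self):
        # integer-arithmetic oracle: enumerate hypergeometric weights exactly
        for r1 in range(1, 13):
            for r2 in range(1, 13):
                for n1 in range(0, r1 + r2 + 1):
                    lo, hi = max(0, n1 - r2), min(r1, n1)
                    ws = [
                        math.comb(r1, k) * math.comb(r2, n1 - k)
                        for k in range(lo, hi + 1)
                    ]
                    tot = sum(ws)
                    for a in range(lo, hi + 1):
                        expected = sum(w for w in ws if w <= ws[a - lo]) / tot
                        got = fisher_exact(
                            ContingencyTable(a, r1 - a, n1 - a, r2 - (n1 - a))
                        )
                        assert got == pytest.approx(expected, abs=1e-12)


class TestOddsRatio:
    def test_identical_rows_give_unity(self):
        or_, lo, hi = odds_ratio_ci(ContingencyTable(10, 90, 10, 90))
        assert or_ == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_cross_product_formula(self):
        or_, lo, hi = odds_ratio_ci(ContingencyTable(104, 6075, 3, 60703))
        assert or_ == pytest.approx((104 * 60703) / (6075 * 3))
        assert or_ == pytest.approx(346.4, rel=1e-3)

    def test_haldane_anscombe_zero_cell(self):
        or_, _, _ = odds_ratio_ci(ContingencyTable(0, 100, 5, 995))
        assert or_ == pytest.approx((0.5 * 995.5) / (100.5 * 5.5))

    def test_degenerate_row_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            odds_ratio_ci(ContingencyTable(0, 0, 5, 995))

    def test_wider_interval_at_higher_confidence(self):
        t = ContingencyTable(20, 980, 10, 990)
        _, lo95, hi95 = odds_ratio_ci(t, alpha=0.05)
        _, lo99, hi99 = odds_ratio_ci(t, alpha=0.01)
        assert lo99 < lo95 and hi99 > hi95


class TestEtiologicalFraction:
    @pytest.mark.parametrize("orv,ef", [(1.0, 0.0), (2.0, 0.5), (10.0, 0.9)])
    def test_formula(self, orv, ef):
        assert etiological_fraction(orv)[0] == pytest.approx(ef)

    def test_lower_bound_floored_at_zero(self):
        # an OR interval reaching below 1 floors the EF lower bound at 0
        ef, lo, hi = etiological_fraction(1.27, 0.8, 1.8)
        assert lo == 0.0
        assert ef == pytest.approx(0.21, abs=0.005)
        assert hi == pytest.approx(1 - 1 / 1.8)

    def test_strictly_increasing_in_or_with_limits(self):
        grid = np.logspace(0.001, 3, 50)
        efs = [etiological_fraction(v)[0] for v in grid]
        assert all(b > a for a, b in zip(efs, efs[1:]))
        assert etiological_fraction(1.0)[0] == 0.0
        assert etiological_fraction(1e9)[0] == pytest.approx(1.0, abs=1e-8)

    def test_nonpositive_or_rejected(self):
        with pytest.raises(ValueError):
            etiological_fraction(0.0)


class TestMultipleTesting:
    @pytest.mark.parametrize(
        "m,expected", [(20, 0.0025), (8, 0.00625), (1, 0.05)]
    )
    def test_bonferroni_threshold(self, m, expected):
        assert bonferroni_threshold(MultipleTestingPlan(0.05, m)) == pytest.approx(expected)


class TestBinomialCI:
    def test_paper_precision_worked_example(self):
        lo, hi = binomial_ci(104, 6179)
        assert round(100 * lo, 1) == 1.4
        assert round(100 * hi, 1) == 2.0

    def test_boundary_and_symmetry(self):
        lo, _ = binomial_ci(0, 100)
        assert lo == 0.0
        lo, hi = binomial_ci(50, 100)
        assert (lo + hi) / 2 == pytest.approx(0.5, abs=0.01)

    def test_nested_levels(self):
        lo95, hi95 = binomial_ci(30, 200, level=0.95)
        lo99, hi99 = binomial_ci(30, 200, level=0.99)
        assert lo99 < lo95 and hi99 > hi95


class TestPredictedPathogenic:
    @pytest.mark.parametrize(
        "excess,n,expected", [(0.015, 1000, 15.0), (-0.002, 1000, 0.0), (0.0, 500, 0.0)]
    )
    def test_floored_product(self, excess, n, expected):
        assert predicted_pathogenic(excess, n) == expected


class TestRunBurden:
    def _run(self, seed, pathogenic_fraction=0.0, n_cases=1000, n_ref=60000):
        specs = [
            SyntheticGeneSpec(
                gene="G1",
                protein_length=1000,
                background_rate=0.02,
                pathogenic_fraction=pathogenic_fraction,
            )
        ]
        cases, ref, panel, truth = generate(specs, n_cases, n_ref, seed=seed)
        kc, ks = filter_rare(cases, ref)
        return (
            run_burden("synthetic_disease", kc, ks, panel, all_reference_sites=ref),
            truth,
        )

    def test_classes_partition_carrier_counts(self):
        results, _ = self._run(seed=11, pathogenic_fraction=0.02)
        by_class = {r.variant_class: r for r in results}
        assert by_class[ALL_CLASSES].case_carriers == pytest.approx(
            by_class["truncating"].case_carriers
            + by_class["nontruncating"].case_carriers
        )

    def test_null_gene_has_small_excess_and_ef(self):
        # no pathogenic injection: case excess within binomial sampling noise
        excesses, efs = [], []
        for seed in range(12):
            results, _ = self._run(seed=100 + seed)
            r = next(x for x in results if x.variant_class == ALL_CLASSES)
            excesses.append(r.case_excess)
            efs.append(r.ef_point)
        se = math.sqrt(0.02 * 0.98 / 1000)
        assert abs(float(np.mean(excesses))) < 3 * se / math.sqrt(12)
        assert float(np.mean(efs)) < 0.25

    def test_true_or_recovered_within_ci(self):
        # gene with a strong implanted effect: the true OR falls inside the
        # reported 95% interval in most replicates
        specs = [
            SyntheticGeneSpec(
                gene="G1",
                protein_length=1000,
                background_rate=0.01,
                pathogenic_fraction=0.10,
            )
        ]
        covered = 0
        n_rep = 20
        for seed in range(n_rep):
            cases, ref, panel, truth = generate(specs, 2000, 60000, seed=300 + seed)
            kc, ks = filter_rare(cases, ref)
            results = run_burden(
                "synthetic_disease", kc, ks, panel, all_reference_sites=ref
            )
            r = next(x for x in results if x.variant_class == ALL_CLASSES)
            t = truth.genes["G1"]
            covered += r.or_lo <= t.true_or <= r.or_hi
        assert covered >= 0.9 * n_rep

    def test_gene_missing_from_panel_is_hard_error(self):
        cases = [CaseVariant("D", "NOVEL", "v", "missense_variant", 1)]
        panel = [PanelEntry("D", "G1", 100, 500)]
        with pytest.raises(ValueError, match="NOVEL"):
            run_burden("D", cases, [], panel, default_an=1000)

    def test_deterministic_given_inputs(self):
        r1, _ = self._run(seed=5, pathogenic_fraction=0.01)
        r2, _ = self._run(seed=5, pathogenic_fraction=0.01)
        assert r1 == r2
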
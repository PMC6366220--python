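import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher
from scipy.stats import ttest_ind

from indelassoc import (
    ContingencyTable,
    build_contingency,
    chi_square_rxc,
    cumulative_scan,
    fisher_exact_rxc,
    freeman_halton_p,
    genotype_effect,
    select_and_test,
    simulate_cohort,
)
from indelassoc.errors import (
    EmptyTableError,
    EnumerationCapacityError,
    InsufficientGroupsError,
)
from indelassoc.simulate import LocusSpec, null_effect

from conftest import cohort_from_class_table


def make_table(counts, row_prefix="r", col_prefix="c"):
    counts = np.asarray(counts)
    return ContingencyTable(
        counts,
        tuple(f"{row_prefix}{i}" for i in range(counts.shape[0])),
        tuple(f"{col_prefix}{j}" for j in range(counts.shape[1])),
    )


class TestBuildContingency:
    def test_binary_classing_matches_published_margins(self, goat_10bp_binary_table):
        # reconstruct per-animal records from the class table, then re-derive it
        per_class = [[532, 84, 1], [376, 114, 2], [11, 2, 0]]
        cohort = cohort_from_class_table(per_class)
        table = build_contingency(cohort, "P3_10bp", classing="binary")
        assert table.counts.tolist() == goat_10bp_binary_table.tolist()
        assert table.row_labels == ("litter=1", "litter>=2")

    def test_per_class_classing(self, goat_10bp_class_table):
        cohort = cohort_from_class_table(goat_10bp_class_table)
        table = build_contingency(cohort, "P3_10bp", classing="per-class")
        assert table.counts.tolist() == goat_10bp_class_table.tolist()

    def test_single_class_cohort_degenerates_to_p_one(self):
        cohort = cohort_from_class_table([[10, 5, 2]])  # only single-lamb mothers
        table = build_contingency(cohort, "P3_10bp", classing="binary")
        res = select_and_test(table)
        assert res.degenerate and res.p_value == 1.0

    def test_no_complete_data_rejected(self):
        from indelassoc import AnimalRecord, Cohort, IndelLocus

        cohort = Cohort(
            (IndelLocus("L1"),),
            (AnimalRecord("a1", {"L1": "II"}),),  # genotype but no phenotype
        )
        with pytest.raises(EmptyTableError):
            build_contingency(cohort, "L1")


class TestChiSquare:
    def test_published_subset_row(self):
        res = chi_square_rxc(make_table([[15, 70, 167], [14, 77, 158]]))
        assert res.df == 2
        assert res.p_value == pytest.approx(0.741, abs=2e-3)

    def test_proportional_rows_give_zero_statistic(self):
        res = chi_square_rxc(make_table([[10, 20, 30], [20, 40, 60]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == 1.0

    def test_diagonal_table_direct_arithmetic(self):
        # oracle: every expected cell is 5, so the statistic is 4 * 25/5 = 20
        res = chi_square_rxc(make_table([[10, 0], [0, 10]]))
        assert res.statistic == pytest.approx(20.0)
        assert res.df == 1

    def test_zero_column_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            res = chi_square_rxc(make_table([[10, 0, 5], [8, 0, 7]]))
        assert res.df == 1

    def test_permutation_invariance(self):
        t = np.array([[5, 9, 2], [7, 1, 6]])
        base = chi_square_rxc(make_table(t)).statistic
        assert chi_square_rxc(make_table(t[::-1])).statistic == pytest.approx(base)
        assert chi_square_rxc(make_table(t[:, ::-1])).statistic == pytest.approx(base)


class TestFreemanHalton:
    def test_small_2x2_enumeration(self):
        assert freeman_halton_p([[3, 1], [1, 3]]) == pytest.approx(0.4857, abs=2e-4)

    def test_published_2x3_headline_value(self, goat_10bp_binary_table):
        p = freeman_halton_p(goat_10bp_binary_table)
        assert p == pytest.approx(6.030e-5, rel=5e-3)

    def test_published_3x3_litter_class_value(self, goat_10bp_class_table):
        p = freeman_halton_p(goat_10bp_class_table)
        assert p == pytest.approx(4.447e-4, rel=5e-3)

    def test_degenerate_single_column_gives_one(self):
        assert freeman_halton_p([[5], [3]]) == 1.0
        res = fisher_exact_rxc(make_table([[5, 0], [3, 0]]))
        assert res.degenerate and res.p_value == 1.0

    def test_zero_column_reduced_before_testing(self):
        with_zero = freeman_halton_p([[3, 0, 1], [1, 0, 3]])
        assert with_zero == pytest.approx(freeman_halton_p([[3, 1], [1, 3]]))

    def test_permutation_invariance(self):
        t = np.array([[4, 2, 7], [1, 8, 3], [5, 5, 0]])
        base = freeman_halton_p(t)
        assert freeman_halton_p(t[[2, 0, 1]]) == pytest.approx(base, rel=1e-9)
        assert freeman_halton_p(t[:, [1, 2, 0]]) == pytest.approx(base, rel=1e-9)
        assert freeman_halton_p(t.T) == pytest.approx(base, rel=1e-9)

    def test_capacity_guard(self):
        big = np.full((6, 6), 400)
        with pytest.raises(EnumerationCapacityError):
            freeman_halton_p(big)

    def test_matches_classical_fisher_on_random_2x2(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            t = rng.integers(0, 13, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            ours = freeman_halton_p(t)
            ref = scipy_fisher(t).pvalue
            assert ours == pytest.approx(ref, rel=1e-8, abs=1e-12)

    def test_agrees_with_chi_square_on_well_filled_tables(self):
        # sanity: with all expected counts >= 5 the exact and asymptotic
        # p-values agree within a factor of 2
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 20:
            t = rng.integers(10, 60, size=(2, 3))
            table = make_table(t)
            if table.expected().min() < 5:
                continue
            p_exact = fisher_exact_rxc(table).p_value
            p_chi = chi_square_rxc(table).p_value
            if p_chi < 1e-3:  # deep-tail ratios are not what this checks
                continue
            assert 0.5 <= p_exact / p_chi <= 2.0
            checked += 1


class TestSelectAndTest:
    def test_switches_to_chi_square_when_cells_well_filled(self):
        res = select_and_test(make_table([[15, 70, 167], [14, 77, 158]]))
        assert res.test_used == "chi_square"
        # smallest expected count: 29 * 249 / 501
        assert res.min_expected == pytest.approx(29 * 249 / 501, rel=1e-9)

    def test_switches_to_exact_when_expected_below_five(self, goat_10bp_binary_table):
        res = select_and_test(make_table(goat_10bp_binary_table))
        assert res.test_used == "fisher_exact"
        assert res.min_expected < 5

    def test_forced_fisher_override(self):
        res = select_and_test(make_table([[15, 70, 167], [14, 77, 158]]), rule="fisher")
        assert res.test_used == "fisher_exact"


class TestCumulativeScan:
    @pytest.fixture
    def cohort(self):
        return simulate_cohort(
            450,
            [LocusSpec("L1", p_I=0.3)],
            effect=null_effect(),
            seed=99,
        )

    def test_final_stage_equals_full_cohort_test(self, cohort):
        stages = cumulative_scan(cohort, "L1", step=100, seed=5)
        full = select_and_test(build_contingency(cohort, "L1"))
        assert stages[-1].n == len(cohort)
        assert stages[-1].p_value == full.p_value
        assert stages[-1].test_used == full.test_used

    def test_stage_sizes_step_then_exhaust(self, cohort):
        stages = cumulative_scan(cohort, "L1", step=100, seed=5)
        assert [s.n for s in stages] == [100, 200, 300, 400, 450]

    def test_published_panel_geometry(self, goat_10bp_class_table):
        cohort = cohort_from_class_table(goat_10bp_class_table)
        stages = cumulative_scan(cohort, "P3_10bp", step=100, seed=1)
        assert [s.n for s in stages] == [*range(100, 1200, 100), 1122]

    def test_same_seed_bit_reproducible(self, cohort):
        a = cumulative_scan(cohort, "L1", step=100, seed=17)
        b = cumulative_scan(cohort, "L1", step=100, seed=17)
        assert a == b

    def test_different_seeds_share_final_entry(self, cohort):
        a = cumulative_scan(cohort, "L1", step=100, seed=1)
        b = cumulative_scan(cohort, "L1", step=100, seed=2)
        assert a[-1] == b[-1]
        assert a[:-1] != b[:-1]  # intermediate subsets differ

    def test_invalid_step_rejected(self, cohort):
        with pytest.raises(ValueError):
            cumulative_scan(cohort, "L1", step=0)

    def test_null_effect_type_I_error_calibrated(self):
        """Under no genotype effect the final-stage test rejects at ~5%."""
        hits = 0
        reps = 500
        for seed in range(reps):
            cohort = simulate_cohort(
                400,
                [LocusSpec("L1", p_I=0.3)],
                effect=null_effect(),
                seed=10_000 + seed,
            )
            res = select_and_test(build_contingency(cohort, "L1"))
            hits += res.p_value < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.02)


class TestGenotypeEffect:
    def test_published_group_means_and_t_test(self, goat_10bp_class_table):
        cohort = cohort_from_class_table(goat_10bp_class_table)
        eff = genotype_effect(cohort, "P3_10bp", min_n=5)
        by_g = {g.genotype: g for g in eff.groups}
        assert round(by_g["II"].lsm, 2) == 1.43
        assert by_g["ID"].lsm == pytest.approx(1.59)
        assert eff.excluded == (("DD", 3, "n = 3 < 5"),)
        (cmp,) = eff.comparisons
        assert cmp.label == "II vs ID"
        assert cmp.p_value == pytest.approx(1.103e-4, rel=0.01)

    def test_identical_groups_give_t_zero_p_one(self):
        cohort = cohort_from_class_table([[5, 5, 0], [5, 5, 0]])
        eff = genotype_effect(cohort, "P3_10bp")
        (cmp,) = eff.comparisons
        assert cmp.t == 0.0 and cmp.p_value == 1.0

    def test_pooled_t_matches_scipy_oracle(self):
        # groups {1,1,2,2,2} vs {1,2,2,2,2}
        cohort = cohort_from_class_table([[2, 1, 0], [3, 4, 0]])
        eff = genotype_effect(cohort, "P3_10bp", min_n=5)
        (cmp,) = eff.comparisons
        ref = ttest_ind([1, 1, 2, 2, 2], [1, 2, 2, 2, 2], equal_var=True)
        assert cmp.t == pytest.approx(ref.statistic)
        assert cmp.p_value == pytest.approx(ref.pvalue)
        assert cmp.df == 8

    def test_welch_option(self):
        cohort = cohort_from_class_table([[8, 2, 0], [4, 9, 0]])
        eff = genotype_effect(cohort, "P3_10bp", welch=True)
        ref = ttest_ind([1] * 8 + [2] * 4, [1] * 2 + [2] * 9, equal_var=False)
        assert eff.comparisons[0].p_value == pytest.approx(ref.pvalue)

    def test_group_means_invariant_to_record_order(self, goat_10bp_class_table):
        from indelassoc import Cohort

        cohort = cohort_from_class_table(goat_10bp_class_table)
        reversed_cohort = Cohort(cohort.loci, tuple(reversed(cohort.animals)))
        a = genotype_effect(cohort, "P3_10bp")
        b = genotype_effect(reversed_cohort, "P3_10bp")
        for ga, gb in zip(a.groups, b.groups):
            assert (ga.genotype, ga.n) == (gb.genotype, gb.n)
            assert ga.lsm == pytest.approx(gb.lsm, rel=1e-12)
            assert ga.se == pytest.approx(gb.se, rel=1e-12)

    def test_insufficient_groups_rejected(self):
        cohort = cohort_from_class_table([[10, 2, 0], [12, 1, 0]])
        with pytest.raises(InsufficientGroupsError):
            genotype_effect(cohort, "P3_10bp", min_n=5)
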
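"""Allele-burden counting and group-mean comparison statistics."""

import math

import numpy as np
import pytest

from rircd import (
    Affection,
    Cohort,
    Individual,
    burden_table,
    compare_group_means,
    individual_allele_count,
    simulate_burden_power,
)
from rircd.synthetic import SimulationConfig, simulate_cohort


class TestAlleleCount:
    def test_mt_plus_heterozygous_nuclear_gives_two(self):
        # the typical digenic patient: homoplasmic mtDNA variant + one het modifier
        ind = Individual(id="A", family_id="F", mt_carrier=True)
        cohort = Cohort(individuals=[ind], genotypes={("A", "v"): 1},
                        qualifying_variants={"v"})
        assert individual_allele_count(ind, cohort) == 2

    def test_triallelic_severe_case(self):
        # mt variant + het variants in two different modifier genes -> 3
        ind = Individual(id="A", family_id="F", mt_carrier=True)
        cohort = Cohort(individuals=[ind],
                        genotypes={("A", "vE"): 1, ("A", "vT"): 1},
                        qualifying_variants={"vE", "vT"})
        assert individual_allele_count(ind, cohort) == 3

    def test_no_variants_no_mt_is_zero(self):
        ind = Individual(id="A", family_id="F")
        cohort = Cohort(individuals=[ind], qualifying_variants={"v"})
        assert individual_allele_count(ind, cohort) == 0

    def test_counts_match_brute_force_on_seeded_cohort(self):
        cohort, _, truth = simulate_cohort(SimulationConfig(seed=9, n_families=8))
        truth = truth.set_index("individual_id")
        for ind in cohort.individuals:
            expected = sum(
                count for (iid, vid), count in cohort.genotypes.items()
                if iid == ind.id and vid in cohort.qualifying_variants
            ) + (1 if ind.mt_carrier else 0)
            assert individual_allele_count(ind, cohort) == expected
            # and the generator's ground truth agrees on the nuclear part
            assert truth.loc[ind.id, "modifier_alleles"] == expected - int(ind.mt_carrier)


class TestBurdenTable:
    def test_rows_match_individual_counts(self, small_cohort):
        table = burden_table(small_cohort)
        assert len(table) == 4
        by_id = table.set_index("individual_id")["allele_count"]
        assert by_id["P1"] == 2 and by_id["P3"] == 3 and by_id["P4"] == 1

    def test_empty_cohort(self):
        table = burden_table(Cohort(individuals=[]))
        assert table.empty and list(table.columns) == [
            "individual_id", "family_id", "group", "allele_count"
        ]

    def test_group_means_match_hand_computation(self):
        cohort, _, _ = simulate_cohort(SimulationConfig(seed=21, n_families=9))
        table = burden_table(cohort)
        for group, sub in table.groupby("group"):
            assert sub["allele_count"].mean() == pytest.approx(
                sum(sub["allele_count"]) / len(sub)
            )


class TestCompareGroupMeans:
    def test_identical_groups(self):
        res = compare_group_means([1, 2, 3], [1, 2, 3])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_pooled_t_matches_hand_arithmetic(self):
        # groups [0,1,1,2] vs [2,3,3,4]: means 1, 3; pooled var 2/3;
        # SE = sqrt(2/3 * 1/2) = 1/sqrt(3); t = -2*sqrt(3); df = 6
        res = compare_group_means([0, 1, 1, 2], [2, 3, 3, 4], method="student_t")
        assert res.t_statistic == pytest.approx(-2 * math.sqrt(3), abs=1e-12)
        assert res.degrees_of_freedom == 6
        from scipy import stats
        assert res.p_value == pytest.approx(2 * stats.t.sf(2 * math.sqrt(3), 6), abs=1e-12)

    def test_zero_variance_unequal_means(self):
        res = compare_group_means([1, 1, 1], [2, 2, 2])
        assert res.p_value > 0 and res.p_value < 1e-300

    def test_permutation_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            compare_group_means([1, 2], [3, 4], method="permutation")

    def test_permutation_seed_determinism(self):
        a, b = [0, 1, 1, 2, 0, 1], [2, 3, 1, 4, 2, 2]
        r1 = compare_group_means(a, b, method="permutation", n_perm=500, seed=4)
        r2 = compare_group_means(a, b, method="permutation", n_perm=500, seed=4)
        assert r1.p_value == r2.p_value

    def test_permutation_agrees_with_t_on_gaussian_counts(self):
        rng = np.random.default_rng(12)
        a = rng.normal(2.0, 1.0, size=25)
        b = rng.normal(1.2, 1.0, size=25)
        t_res = compare_group_means(a, b, method="student_t")
        p_res = compare_group_means(a, b, method="permutation", n_perm=20_000, seed=12)
        assert p_res.p_value == pytest.approx(t_res.p_value, abs=0.02)

    def test_location_shift_invariance(self):
        # adding the mtDNA allele to every member of both groups leaves t unchanged
        rng = np.random.default_rng(2)
        a = rng.poisson(1.5, size=15)
        b = rng.poisson(1.0, size=12)
        base = compare_group_means(a, b)
        shifted = compare_group_means(a + 1, b + 1)
        assert shifted.t_statistic == pytest.approx(base.t_statistic, abs=1e-12)
        assert shifted.p_value == pytest.approx(base.p_value, abs=1e-12)


class TestPower:
    FREQS = [0.0135, 0.09695, 0.05, 0.06, 0.059, 0.04]

    def test_null_type_one_error_calibrated(self):
        res = simulate_burden_power(self.FREQS, group_sizes=(22, 12), effect_size=0.0,
                                    n_sims=600, seed=8)
        se = max(res["mc_se"], math.sqrt(0.05 * 0.95 / res["n_sims"]))
        assert abs(res["power"] - 0.05) <= 3 * se

    def test_power_self_consistent_across_seeds(self):
        r1 = simulate_burden_power(self.FREQS, group_sizes=(22, 12), effect_size=1.0,
                                   n_sims=1000, seed=1)
        r2 = simulate_burden_power(self.FREQS, group_sizes=(22, 12), effect_size=1.0,
                                   n_sims=1000, seed=2)
        se = math.sqrt(r1["mc_se"] ** 2 + r2["mc_se"] ** 2)
        assert abs(r1["power"] - r2["power"]) <= 3 * max(se, 1e-3)

    def test_power_monotone_in_effect_size(self):
        powers = [
            simulate_burden_power(self.FREQS, group_sizes=(22, 12), effect_size=e,
                                  n_sims=400, seed=5)["power"]
            for e in (0.0, 0.5, 1.0)
        ]
        assert powers[0] <= powers[1] <= powers[2]
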
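"""Carrier-frequency, co-occurrence, penetrance and prevalence arithmetic."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rircd import (
    FrequencyEntry,
    FrequencyTable,
    carrier_frequency,
    co_occurrence_probability,
    expected_cases,
    maf_from_carrier_counts,
    one_in,
    predicted_penetrance,
    predicted_prevalence,
)
from rircd.synthetic import SimulationConfig, simulate_control_genotypes


def enumerate_carrier_probability(mafs, qualifier):
    """Exhaustive diplotype enumeration oracle: sum over all genotype vectors
    of P(genotype) * [qualifier(genotype)], genotypes HWE-independent."""
    total = 0.0
    for counts in itertools.product((0, 1, 2), repeat=len(mafs)):
        p = 1.0
        for g, maf in zip(counts, mafs):
            hw = {0: (1 - maf) ** 2, 1: 2 * maf * (1 - maf), 2: maf**2}[g]
            p *= hw
        if qualifier(counts):
            total += p
    return total


class TestCarrierFrequency:
    def test_empty_list_is_zero_for_all_methods(self):
        for method in ("additive", "hardy_weinberg_het", "at_least_one_allele"):
            assert carrier_frequency([], method) == 0.0

    def test_at_least_one_allele_matches_enumeration(self):
        mafs = [0.001, 0.002]
        got = carrier_frequency(mafs, "at_least_one_allele")
        assert got == pytest.approx(1 - (0.999**2) * (0.998**2), abs=1e-15)
        oracle = enumerate_carrier_probability(mafs, lambda c: sum(c) >= 1)
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_hardy_weinberg_het_matches_enumeration(self):
        mafs = [0.1, 0.05, 0.01]
        got = carrier_frequency(mafs, "hardy_weinberg_het")
        oracle = enumerate_carrier_probability(mafs, lambda c: any(g == 1 for g in c))
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_additive_reproduces_cumulative_maf(self):
        # six rare alleles summing to the reported cumulative carrier frequency
        mafs = [0.0030, 0.0025, 0.0020, 0.0020, 0.0020, 0.0020]
        assert carrier_frequency(mafs, "additive") == pytest.approx(0.0135)

    def test_out_of_range_maf_rejected(self):
        with pytest.raises(ValueError):
            carrier_frequency([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=0.2, allow_nan=False),
                    min_size=1, max_size=6))
    @settings(deadline=None, derandomize=True)
    def test_diplotype_union_bound(self, mafs):
        # P(>=1 allele over the diplotype) <= sum of per-allele probabilities (2p each)
        add = carrier_frequency(mafs, "additive")
        aloa = carrier_frequency(mafs, "at_least_one_allele")
        hw = carrier_frequency(mafs, "hardy_weinberg_het")
        assert 0 <= aloa <= min(1.0, 2 * add) + 1e-12
        assert hw <= aloa + 1e-12  # het-only carriers are a subset

    def test_diplotype_methods_agree_in_rare_limit(self):
        # as maf -> 0 the diplotype probability 1-prod(1-p)^2 approaches 2*sum(p)
        mafs = [1e-4, 5e-5, 1e-4]
        add = carrier_frequency(mafs, "additive")
        aloa = carrier_frequency(mafs, "at_least_one_allele")
        assert abs(2 * add - aloa) / (2 * add) < 1e-3


class TestCoOccurrence:
    def test_mt_by_rare_modifier_product(self):
        assert co_occurrence_probability(0.0001, 0.0135) == pytest.approx(1.35e-6)

    def test_mt_by_common_modifier_product(self):
        got = co_occurrence_probability(0.0001, 0.09695)
        assert got == pytest.approx(9.695e-6)
        assert round(got, 5) == pytest.approx(1e-5)  # one significant figure

    def test_zero_annihilates(self):
        assert co_occurrence_probability(0.7, 0.0) == 0.0

    def test_monotone_in_each_argument(self):
        base = co_occurrence_probability(0.0001, 0.1)
        assert co_occurrence_probability(0.0002, 0.1) >= base
        assert co_occurrence_probability(0.0001, 0.2) >= base


class TestPenetrancePrevalence:
    def panel(self, mafs):
        return FrequencyTable(
            [FrequencyEntry("G", f"v{i}", m) for i, m in enumerate(mafs)]
        )

    def test_panel_cumulative_penetrance(self):
        mafs = [0.0135, 0.09695 + 0.0005, 0.05, 0.06, 0.05905, 0.04]
        assert sum(mafs) == pytest.approx(0.32)
        assert predicted_penetrance(self.panel(mafs), "additive") == pytest.approx(0.32)

    def test_zero_panel(self):
        assert predicted_penetrance(self.panel([0.0, 0.0])) == 0.0

    def test_additive_vs_at_least_one_inclusion_exclusion(self):
        mafs = [0.1, 0.05]
        add = predicted_penetrance(self.panel(mafs), "additive")
        aloa = predicted_penetrance(self.panel(mafs), "at_least_one_allele")
        oracle = enumerate_carrier_probability(mafs, lambda c: sum(c) >= 1)
        assert aloa == pytest.approx(oracle, abs=1e-12)
        # the conventions differ by inclusion-exclusion: the per-allele union
        # bound 2*additive strictly overcounts multi-allele carriers
        assert aloa < 2 * add

    def test_prevalence_reproduces_one_in_30000(self):
        prev = predicted_prevalence(0.0001, 0.30)
        assert prev == pytest.approx(3e-5)
        assert prev * 100 == pytest.approx(0.003)  # percent scale
        assert one_in(prev) == "1 in 30,000"

    def test_prevalence_identity_at_full_penetrance(self):
        assert predicted_prevalence(0.42, 1.0) == pytest.approx(0.42)

    def test_prevalence_hand_arithmetic(self):
        assert predicted_prevalence(0.0001, 0.32) == pytest.approx(3.2e-5)

    def test_expected_cases_uk_scale(self):
        assert expected_cases(1 / 30_000, 66_000_000) == pytest.approx(2200)
        assert expected_cases(1 / 30_000, 66_000_000) >= 2000
        assert expected_cases(3e-5, 10**6) == pytest.approx(30)
        assert expected_cases(0.0, 10**6) == 0.0

    def test_one_in_zero_prevalence(self):
        assert one_in(0.0) == "1 in inf"


class TestMafFromCarrierCounts:
    def test_biobank_homoplasmic_count(self):
        maf = maf_from_carrier_counts(11, 358_916, "haploid_mt")
        assert maf == pytest.approx(11 / 358_916, rel=1e-12)
        assert maf == pytest.approx(3.06e-5, rel=1e-2)
        assert float(f"{maf:.0e}") == pytest.approx(3e-5)  # one significant figure

    def test_zero_carriers(self):
        assert maf_from_carrier_counts(0, 1000) == 0.0

    def test_autosomal_counting_oracle(self):
        # 5 heterozygous carriers in 100 individuals: 5 alleles / 200 chromosomes
        alleles = sum([1] * 5)
        assert maf_from_carrier_counts(alleles, 100, "autosomal") == pytest.approx(0.025)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            maf_from_carrier_counts(5, 0)
        with pytest.raises(ValueError):
            maf_from_carrier_counts(1001, 1000, "haploid_mt")


class TestRoundTrip:
    def test_simulated_frequencies_recovered_within_3se(self):
        """Simulate control genotypes, re-estimate each variant's MAF from the
        table, compare to the generating frequency within 3 binomial SE."""
        config = SimulationConfig(seed=17, n_controls=5000)
        table = simulate_control_genotypes(config)
        n = config.n_controls
        counts = table.groupby("variant_id")["allele_count"].sum()
        for entry in config.panel.entries:
            observed = int(counts.get(entry.variant_id, 0))
            est = maf_from_carrier_counts(observed, n, "autosomal")
            se = math.sqrt(entry.maf * (1 - entry.maf) / (2 * n))
            assert abs(est - entry.maf) <= 3 * se + 1e-9, entry.variant_id
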
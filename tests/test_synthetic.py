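"""Generator properties: determinism, transmission rules, penetrance recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from rircd import (
    Affection,
    PenetranceModel,
    SimulationConfig,
    carrier_frequency,
    simulate_assay_tables,
    simulate_cohort,
    simulate_control_genotypes,
)
from rircd.synthetic import default_panel_frequencies, synthetic_mt_proteome


class TestDeterminism:
    def test_identical_seed_identical_cohort(self):
        c1, v1, t1 = simulate_cohort(SimulationConfig(seed=99))
        c2, v2, t2 = simulate_cohort(SimulationConfig(seed=99))
        assert c1.genotypes == c2.genotypes
        assert [i.id for i in c1.individuals] == [i.id for i in c2.individuals]
        assert [i.affection for i in c1.individuals] == [i.affection for i in c2.individuals]
        pd.testing.assert_frame_equal(t1, t2)

    def test_identical_seed_identical_tables(self):
        cfg = SimulationConfig(seed=5)
        ct1, pr1 = simulate_assay_tables(cfg)
        ct2, pr2 = simulate_assay_tables(cfg)
        pd.testing.assert_frame_equal(ct1, ct2)
        pd.testing.assert_frame_equal(pr1, pr2)
        g1 = simulate_control_genotypes(cfg)
        g2 = simulate_control_genotypes(cfg)
        pd.testing.assert_frame_equal(g1, g2)

    def test_different_seeds_differ(self):
        g1 = simulate_control_genotypes(SimulationConfig(seed=1, n_controls=200))
        g2 = simulate_control_genotypes(SimulationConfig(seed=2, n_controls=200))
        assert not g1.equals(g2)

    def test_components_use_independent_substreams(self):
        cfg = SimulationConfig(seed=7)
        # drawing assays first must not perturb the cohort stream
        simulate_assay_tables(cfg)
        c1, _, _ = simulate_cohort(cfg)
        c2, _, _ = simulate_cohort(SimulationConfig(seed=7))
        assert c1.genotypes == c2.genotypes


class TestTransmission:
    def test_maternal_mtdna_transmission(self):
        cohort, _, _ = simulate_cohort(SimulationConfig(seed=3, n_families=12))
        by_id = {i.id: i for i in cohort.individuals}
        for ind in cohort.individuals:
            if ind.mother_id:
                assert ind.mt_carrier == by_id[ind.mother_id].mt_carrier

    def test_freq_mt_zero_means_no_carriers(self):
        cfg = SimulationConfig(seed=4, freq_mt=0.0, founder_mothers_carry_mt=False)
        cohort, _, truth = simulate_cohort(cfg)
        assert not any(i.mt_carrier for i in cohort.individuals)

    def test_children_alleles_bounded_by_parents(self):
        cohort, _, _ = simulate_cohort(SimulationConfig(seed=8, n_families=10))
        for ind in cohort.individuals:
            if not ind.mother_id:
                continue
            for vid in cohort.qualifying_variants:
                child = cohort.allele_count(ind.id, vid)
                m = cohort.allele_count(ind.mother_id, vid)
                f = cohort.allele_count(ind.father_id, vid)
                # Mendelian: at most one allele per parent, needs a carrier parent
                assert child <= (m > 0) + (f > 0)


class TestPenetranceModel:
    def test_degenerate_penetrance_only_digenic_affected(self):
        cfg = SimulationConfig(
            seed=6,
            n_families=40,
            penetrance=PenetranceModel(pi_digenic=1.0, pi_mt_only=0.0, pi_background=0.0),
        )
        cohort, _, truth = simulate_cohort(cfg)
        affected = truth[truth["affected"]]
        assert len(affected) > 0
        assert (affected["mt_carrier"] & affected["has_modifier"]).all()

    def test_carrier_fraction_matches_binomial_oracle(self):
        """10,000 founders at the panel MAFs: modifier-carrier fraction within
        3 binomial SE of the at-least-one-allele closed form."""
        cfg = SimulationConfig(seed=15, n_controls=10_000)
        table = simulate_control_genotypes(cfg)
        carriers = table["individual_id"].nunique()
        expected = carrier_frequency(cfg.panel.mafs, "at_least_one_allele")
        se = math.sqrt(expected * (1 - expected) / cfg.n_controls)
        assert abs(carriers / cfg.n_controls - expected) <= 3 * se

    def test_penetrance_recovery_large_cohort(self):
        """Estimated penetrance among mt carriers matches
        cf*pi_digenic + (1-cf)*pi_mt_only within 3 binomial SE."""
        cfg = SimulationConfig(seed=23, n_families=2600, children_per_family=1)
        cohort, _, truth = simulate_cohort(cfg)
        carriers = truth[truth["mt_carrier"]]
        assert len(carriers) >= 5000
        est = carriers["affected"].mean()
        cf = carrier_frequency(cfg.panel.mafs, "at_least_one_allele")
        expected = cf * cfg.penetrance.pi_digenic + (1 - cf) * cfg.penetrance.pi_mt_only
        se = math.sqrt(expected * (1 - expected) / len(carriers))
        assert abs(est - expected) <= 3 * se

    def test_burden_separation_about_one_allele(self):
        """Affected-vs-unaffected carrier mean burden differs by about one
        allele under study-condition defaults."""
        from rircd import burden_table

        cfg = SimulationConfig(seed=31)
        cohort, _, _ = simulate_cohort(cfg)
        table = burden_table(cohort)
        carriers = {i.id for i in cohort.individuals if i.mt_carrier}
        table = table[table["individual_id"].isin(carriers)]
        means = table.groupby("group")["allele_count"].mean()
        diff = means["affected"] - means["unaffected"]
        assert 0.5 < diff < 2.0


class TestControls:
    def test_maf_zero_all_absent(self):
        cfg = SimulationConfig(seed=1, n_controls=50)
        panel = default_panel_frequencies()
        from rircd.digenic import FrequencyEntry, FrequencyTable
        zero = FrequencyTable([FrequencyEntry(e.gene, e.variant_id, 0.0) for e in panel.entries])
        table = simulate_control_genotypes(
            SimulationConfig(seed=1, n_controls=50, panel=zero)
        )
        assert table.empty

    def test_maf_one_all_homozygous(self):
        from rircd.digenic import FrequencyEntry, FrequencyTable
        one = FrequencyTable([FrequencyEntry("G", "v", 1.0)])
        table = simulate_control_genotypes(SimulationConfig(seed=1, n_controls=20, panel=one))
        assert len(table) == 20
        assert (table["allele_count"] == 2).all()


class TestSyntheticProteome:
    def test_sequences_deterministic_and_match_declared_composition(self):
        from rircd.synthetic import MT_PROTEIN_EQ, MT_PROTEIN_LENGTHS

        seqs = dict(synthetic_mt_proteome())
        assert seqs == dict(synthetic_mt_proteome())
        for gene, seq in seqs.items():
            assert len(seq) == MT_PROTEIN_LENGTHS[gene]
            e, q = MT_PROTEIN_EQ[gene]
            assert seq.count("E") == e and seq.count("Q") == q
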
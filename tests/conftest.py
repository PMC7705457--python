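import pytest

from rircd import (
    Affection,
    AnnotatedVariant,
    Cohort,
    Consequence,
    Individual,
    SimulationConfig,
)


def make_variant(vid="v1", consequence=Consequence.MISSENSE, maf=0.001, gene="EARS2",
                 damaging=True, conserved=True, in_domain=True, **kw):
    return AnnotatedVariant(
        id=vid, contig=kw.pop("contig", "chr16"), position=kw.pop("position", 100),
        ref_allele="A", alt_allele="G", gene=gene, consequence=consequence,
        predicted_damaging=damaging, conserved=conserved, in_domain=in_domain,
        population_maf=maf, **kw,
    )


@pytest.fixture
def small_cohort():
    """Three-person family plus one unrelated: two qualifying variants."""
    individuals = [
        Individual(id="P1", family_id="F1", affection=Affection.AFFECTED, mt_carrier=True),
        Individual(id="P2", family_id="F1", affection=Affection.UNAFFECTED, mt_carrier=True),
        Individual(id="P3", family_id="F1", affection=Affection.AFFECTED, mt_carrier=True),
        Individual(id="P4", family_id="F2", affection=Affection.UNAFFECTED, mt_carrier=False),
    ]
    genotypes = {
        ("P1", "vE"): 1,  # affected carries EARS2 variant
        ("P3", "vE"): 1,
        ("P3", "vT"): 1,
        ("P4", "vT"): 1,  # shared variant: affected P3 and unaffected P4
    }
    return Cohort(
        individuals=individuals,
        genotypes=genotypes,
        qualifying_variants={"vE", "vT"},
        variant_genes={"vE": "EARS2", "vT": "TRMU"},
    )


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=11)
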
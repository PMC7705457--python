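"""Synthetic cohort, genotype, expression and assay-table generators.

Everything downstream consumes tables this module can emit, so the whole
analysis is testable without any external download.  The defaults encode the
study conditions: a homoplasmic mtDNA variant at MAF 1e-4, a six-gene nuclear
modifier panel with cumulative allele frequency 0.32 (EARS2 0.0135, TRMU
p.Ala10Ser 0.09695), 19 two-generation families, 1,044 population controls,
maternal mtDNA transmission, Mendelian nuclear transmission and a digenic
penetrance function (high penetrance with both hits, near-zero otherwise).

All generation is seeded; one root seed deterministically derives independent
per-component substreams, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Affection, Cohort, Individual, Role, Sex
from .composition import CompositionRecord, composition_frame
from .digenic import FrequencyEntry, FrequencyTable
from .variants import MT_CONTIG, AnnotatedVariant, Consequence, Genome

MT_VARIANT_ID = "mt_tRNAGlu_14674"

#: Residue lengths of the 13 human mtDNA-encoded proteins (true lengths).
MT_PROTEIN_LENGTHS: dict[str, int] = {
    "MT-ND1": 318, "MT-ND2": 347, "MT-ND3": 115, "MT-ND4": 459, "MT-ND4L": 98,
    "MT-ND5": 603, "MT-ND6": 174, "MT-CO1": 513, "MT-CO2": 227, "MT-CO3": 261,
    "MT-ATP6": 226, "MT-ATP8": 68, "MT-CYB": 380,
}

#: Target Glu+Gln counts (count_E, count_Q) for the SYNTHETIC proteome
#: fixture: field-plausible fractions with complex I (ND) subunits richer in
#: E/Q and MT-ND5 carrying the highest absolute count.  These are modelling
#: choices, not reference translations.
MT_PROTEIN_EQ: dict[str, tuple[int, int]] = {
    "MT-ND1": (10, 6), "MT-ND2": (12, 9), "MT-ND3": (4, 3), "MT-ND4": (17, 11),
    "MT-ND4L": (4, 3), "MT-ND5": (28, 17), "MT-ND6": (5, 3), "MT-CO1": (13, 7),
    "MT-CO2": (8, 4), "MT-CO3": (8, 4), "MT-ATP6": (7, 4), "MT-ATP8": (4, 2),
    "MT-CYB": (11, 6),
}

_OTHER_AA = "ACDFGHIKLMNPRSTVWY"
# membrane-protein-like background composition (hydrophobic-rich)
_OTHER_WEIGHTS = np.array(
    [8, 2, 3, 6, 7, 2, 6, 5, 10, 11, 5, 6, 5, 3, 7, 8, 2, 4], dtype=float
)


def default_panel_frequencies() -> FrequencyTable:
    """Default modifier-panel allele frequencies.

    Cumulative (additive) totals reproduce the study conditions: EARS2
    0.0135 over six rare variants, TRMU 0.09695 (common p.Ala10Ser-like)
    plus one rare variant, panel-wide 0.32.  The per-variant split within
    those totals is a modelling choice.
    """
    entries = [
        FrequencyEntry("EARS2", "EARS2_v1", 0.0030),
        FrequencyEntry("EARS2", "EARS2_v2", 0.0025),
        FrequencyEntry("EARS2", "EARS2_v3", 0.0020),
        FrequencyEntry("EARS2", "EARS2_v4", 0.0020),
        FrequencyEntry("EARS2", "EARS2_v5", 0.0020),
        FrequencyEntry("EARS2", "EARS2_v6", 0.0020),
        FrequencyEntry("TRMU", "TRMU_Ala10Ser", 0.09695),
        FrequencyEntry("TRMU", "TRMU_v2", 0.0005),
        FrequencyEntry("QRSL1", "QRSL1_v1", 0.0500),
        FrequencyEntry("GOT2", "GOT2_v1", 0.0600),
        FrequencyEntry("GLS", "GLS_v1", 0.05905),
        FrequencyEntry("MSS51", "MSS51_v1", 0.0400),
    ]
    return FrequencyTable(entries, source_label="default panel (cumulative 0.32)")


@dataclass(frozen=True)
class PenetranceModel:
    """P(affected | latent state) for the digenic model."""

    pi_digenic: float = 0.9      # mt carrier with >= 1 modifier allele
    pi_mt_only: float = 0.01     # mt carrier without modifier alleles
    pi_background: float = 0.001  # non-carrier baseline

    def __post_init__(self) -> None:
        for name in ("pi_digenic", "pi_mt_only", "pi_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def prob(self, mt_carrier: bool, has_modifier: bool) -> float:
        if mt_carrier and has_modifier:
            return self.pi_digenic
        if mt_carrier:
            return self.pi_mt_only
        return self.pi_background


@dataclass
class SimulationConfig:
    """Study-condition defaults for all generators; seed is mandatory."""

    seed: int
    n_families: int = 19
    children_per_family: int = 2
    freq_mt: float = 1e-4
    founder_mothers_carry_mt: bool = True  # families ascertained as homoplasmic
    panel: FrequencyTable = field(default_factory=default_panel_frequencies)
    penetrance: PenetranceModel = field(default_factory=PenetranceModel)
    n_controls: int = 1044
    # expression model: metric = intercept + slope * fraction_EQ + N(0, noise^2)
    expression_slope: float = -30.0
    expression_intercept: float = 1.0
    expression_noise: float = 0.4
    # proteome ratio model (distribution centred to match 2-SD cutoffs -2.2/0.98)
    proteome_n: int = 1600
    proteome_mean: float = -0.61
    proteome_sd: float = 0.795
    proteome_n_up: int = 8
    proteome_n_down: int = 8
    # qPCR model: delta-Ct per group = baseline + shift, noise in cycles
    ct_nuclear: float = 25.0
    ct_baseline_delta: float = 8.0
    ct_group_shifts: dict = field(
        default_factory=lambda: {"control": 0.0, "affected": 1.2, "recovered": 4.2}
    )
    ct_noise: float = 0.15
    ct_replicates: int = 3
    ct_samples_per_group: int = 3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("freq_mt",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def rng(self, component: str) -> np.random.Generator:
        """Independent deterministic substream for a named component."""
        child = int(np.random.SeedSequence(
            [self.seed, abs(hash_component(component))]
        ).generate_state(1)[0])
        return np.random.default_rng(child)


def hash_component(name: str) -> int:
    # stable across processes (unlike builtin hash on str)
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def _panel_variant_records(panel: FrequencyTable) -> list[AnnotatedVariant]:
    records = []
    for i, e in enumerate(panel.entries):
        records.append(
            AnnotatedVariant(
                id=e.variant_id,
                contig=f"chr{(i % 22) + 1}",
                position=1000 + i * 1000,
                ref_allele="A",
                alt_allele="G",
                gene=e.gene,
                consequence=Consequence.MISSENSE,
                predicted_damaging=True,
                conserved=True,
                in_domain=True,
                population_maf=e.maf,
                genome=Genome.NUCLEAR,
            )
        )
    records.append(
        AnnotatedVariant(
            id=MT_VARIANT_ID,
            contig=MT_CONTIG,
            position=14674,
            ref_allele="T",
            alt_allele="C",
            gene="MT-TE",
            consequence=Consequence.OTHER,
            predicted_damaging=True,
            conserved=True,
            in_domain=False,
            population_maf=1e-4,
            genome=Genome.MITOCHONDRIAL,
        )
    )
    return records


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, list[AnnotatedVariant], pd.DataFrame]:
    """Simulate pedigrees with maternal mtDNA and Mendelian nuclear transmission.

    Each family has two founders (mother, father) and ``children_per_family``
    children.  Founder nuclear alleles are binomial at the panel MAFs;
    children inherit one allele per parent per site.  The mtDNA variant
    passes from carrier mothers to every child.  Affection is Bernoulli with
    probability from the penetrance model given (mt carrier, modifier count
    >= 1).  Returns the cohort, the annotated variant table and a
    ground-truth frame of each individual's latent state.
    """
    rng = config.rng("cohort")
    variants = _panel_variant_records(config.panel)
    panel_vids = [e.variant_id for e in config.panel.entries]
    mafs = np.array(config.panel.mafs)

    individuals: list[Individual] = []
    genotypes: dict[tuple[str, str], int] = {}
    truth_rows = []

    def founder_alleles() -> np.ndarray:
        return rng.binomial(2, mafs)

    def transmit(parent: np.ndarray) -> np.ndarray:
        # one allele per site: heterozygote transmits with p=1/2
        return np.array([rng.binomial(1, g / 2.0) for g in parent])

    for f in range(1, config.n_families + 1):
        fam = f"F{f}"
        mother_id, father_id = f"{fam}_mother", f"{fam}_father"
        mother_mt = (
            True if config.founder_mothers_carry_mt else bool(rng.random() < config.freq_mt)
        )
        if config.freq_mt == 0:
            mother_mt = False
        mother_g = founder_alleles()
        father_g = founder_alleles()
        members = [
            (mother_id, Sex.FEMALE, None, None, mother_mt, mother_g),
            (father_id, Sex.MALE, None, None, False, father_g),
        ]
        for c in range(1, config.children_per_family + 1):
            child_g = transmit(mother_g) + transmit(father_g)
            sex = Sex.FEMALE if rng.random() < 0.5 else Sex.MALE
            members.append((f"{fam}_child{c}", sex, mother_id, father_id, mother_mt, child_g))
        for iid, sex, mid, fid, mt, g in members:
            has_mod = bool(g.sum() > 0)
            p_aff = config.penetrance.prob(mt, has_mod)
            affected = bool(rng.random() < p_aff)
            individuals.append(
                Individual(
                    id=iid, family_id=fam, sex=sex,
                    affection=Affection.AFFECTED if affected else Affection.UNAFFECTED,
                    mt_carrier=mt, mother_id=mid, father_id=fid, role=Role.FAMILY,
                )
            )
            for vid, count in zip(panel_vids, g):
                if count:
                    genotypes[(iid, vid)] = int(count)
            truth_rows.append(
                {
                    "individual_id": iid, "family_id": fam, "mt_carrier": mt,
                    "modifier_alleles": int(g.sum()), "has_modifier": has_mod,
                    "p_affected": p_aff, "affected": affected,
                }
            )

    cohort = Cohort(
        individuals=individuals,
        genotypes=genotypes,
        qualifying_variants=set(panel_vids),
        variant_genes={e.variant_id: e.gene for e in config.panel.entries},
    )
    return cohort, variants, pd.DataFrame(truth_rows)


def simulate_control_genotypes(config: SimulationConfig) -> pd.DataFrame:
    """Population-control genotype table: independent Binomial(2, maf) draws.

    Columns: individual_id, variant_id, allele_count (only nonzero rows,
    plus a zero sentinel row set is unnecessary — absent means 0).
    mt carrier state is false for all controls.
    """
    rng = config.rng("controls")
    rows = []
    vids = [e.variant_id for e in config.panel.entries]
    mafs = np.array(config.panel.mafs)
    draws = rng.binomial(2, mafs, size=(config.n_controls, len(vids)))
    for i in range(config.n_controls):
        iid = f"CTRL{i + 1}"
        for vid, count in zip(vids, draws[i]):
            if count:
                rows.append({"individual_id": iid, "variant_id": vid, "allele_count": int(count)})
    return pd.DataFrame(rows, columns=["individual_id", "variant_id", "allele_count"])


def control_individuals(config: SimulationConfig) -> list[Individual]:
    return [
        Individual(
            id=f"CTRL{i + 1}", family_id="controls", affection=Affection.UNAFFECTED,
            mt_carrier=False, role=Role.CONTROL,
        )
        for i in range(config.n_controls)
    ]


def simulate_expression(
    comp: Sequence[CompositionRecord] | pd.DataFrame,
    slope: float = -30.0,
    noise: float = 0.4,
    seed: int = 0,
    intercept: float = 1.0,
) -> pd.DataFrame:
    """Per-gene expression change linearly coupled to E+Q fraction.

    metric = intercept + slope * fraction_EQ + N(0, noise^2).  A negative
    slope encodes 'more E+Q -> stronger decrease' on a log2-fold-change
    scale (negative = decreased).
    """
    comp_df = comp if isinstance(comp, pd.DataFrame) else composition_frame(list(comp))
    rng = np.random.default_rng(seed)
    metric = intercept + slope * comp_df["fraction_EQ"].to_numpy()
    if noise > 0:
        metric = metric + rng.normal(0.0, noise, size=len(comp_df))
    return pd.DataFrame({"gene": comp_df["gene"], "metric": metric})


def simulate_assay_tables(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct table and protein-ratio table with ground-truth labels.

    Ct table columns: sample_id, group, replicate_id, ct_b2m, ct_mtnd1; each
    group's delta-Ct is baseline + group shift + noise.  Protein table:
    protein_id, log2_ratio, anova_p, unique_peptides, quantified_in_all,
    truth in {null, up, down}; injected outliers sit at mean -/+ 4 SD with
    significant ANOVA p.
    """
    rng = config.rng("assays")
    ct_rows = []
    for group, shift in config.ct_group_shifts.items():
        for s in range(1, config.ct_samples_per_group + 1):
            sid = f"{group}{s}"
            for r in range(1, config.ct_replicates + 1):
                dct = config.ct_baseline_delta + shift + rng.normal(0.0, config.ct_noise)
                ct_rows.append(
                    {
                        "sample_id": sid, "group": group, "replicate_id": f"r{r}",
                        "ct_b2m": config.ct_nuclear,
                        "ct_mtnd1": config.ct_nuclear - dct,
                    }
                )
    ct_table = pd.DataFrame(ct_rows)

    n_null = config.proteome_n - config.proteome_n_up - config.proteome_n_down
    ratios = rng.normal(config.proteome_mean, config.proteome_sd, size=n_null)
    pvals = rng.uniform(0.0, 1.0, size=n_null)
    rows = [
        {
            "protein_id": f"P{i + 1:05d}", "log2_ratio": float(ratios[i]),
            "anova_p": float(pvals[i]), "unique_peptides": True,
            "quantified_in_all": True, "truth": "null",
        }
        for i in range(n_null)
    ]
    for j in range(config.proteome_n_down):
        rows.append(
            {
                "protein_id": f"DN{j + 1:03d}",
                "log2_ratio": float(config.proteome_mean - 4.0 * config.proteome_sd
                                    - abs(rng.normal(0.0, 0.3))),
                "anova_p": float(rng.uniform(0.0, 0.04)),
                "unique_peptides": True, "quantified_in_all": True, "truth": "down",
            }
        )
    for j in range(config.proteome_n_up):
        rows.append(
            {
                "protein_id": f"UP{j + 1:03d}",
                "log2_ratio": float(config.proteome_mean + 4.0 * config.proteome_sd
                                    + abs(rng.normal(0.0, 0.3))),
                "anova_p": float(rng.uniform(0.0, 0.04)),
                "unique_peptides": True, "quantified_in_all": True, "truth": "up",
            }
        )
    protein_table = pd.DataFrame(rows)
    return ct_table, protein_table


def synthetic_mt_proteome(seed: int = 20_105_364) -> list[tuple[str, str]]:
    """SYNTHETIC stand-in for the 13 mtDNA-encoded protein sequences.

    Each sequence has the true residue length of its protein and a fixed,
    field-plausible number of E and Q residues (``MT_PROTEIN_EQ``); all other
    positions are drawn from a hydrophobic-rich background composition and
    shuffled deterministically.  These are NOT the reference translations —
    they are a composition model sufficient for counting and correlation
    machinery.  Returns (gene, sequence) pairs in panel order.
    """
    rng = np.random.default_rng(seed)
    weights = _OTHER_WEIGHTS / _OTHER_WEIGHTS.sum()
    out = []
    for gene, length in MT_PROTEIN_LENGTHS.items():
        n_e, n_q = MT_PROTEIN_EQ[gene]
        n_other = length - n_e - n_q
        other = rng.choice(list(_OTHER_AA), size=n_other, p=weights)
        residues = np.array(["E"] * n_e + ["Q"] * n_q + list(other))
        rng.shuffle(residues)
        out.append((gene, "".join(residues)))
    return out


def write_synthetic_proteome_fasta(path, seed: int = 20_105_364) -> None:
    """Write the synthetic 13-protein FASTA (the packaged fixture's source)."""
    with open(path, "w") as fh:
        for gene, seq in synthetic_mt_proteome(seed=seed):
            fh.write(f">{gene} synthetic mtDNA-encoded protein stand-in\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def replace_config(config: SimulationConfig, **kwargs) -> SimulationConfig:
    """Functional update helper (dataclasses.replace re-export)."""
    return replace(config, **kwargs)
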
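"""Population-genetics arithmetic for digenic mtDNA-nuclear risk.

A homoplasmic mtDNA variant at allele frequency f_mt (carrier frequency =
allele frequency for homoplasmy) co-occurs with a heterozygous nuclear
modifier allele carried with frequency c_nuc; under independence the digenic
co-occurrence probability is f_mt * c_nuc.  Penetrance among mtDNA carriers
is identified with the modifier carrier frequency (every carrier of at least
one modifier allele expresses the phenotype), prevalence is f_mt * penetrance
and expected case counts scale prevalence by population size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

CarrierMethod = Literal["additive", "hardy_weinberg_het", "at_least_one_allele"]

#: Default population size for expected-case projections (UK-scale).
DEFAULT_POPULATION = 66_000_000


@dataclass(frozen=True)
class FrequencyEntry:
    gene: str
    variant_id: str
    maf: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"{self.gene}/{self.variant_id}: MAF {self.maf} outside [0, 1]")


@dataclass
class FrequencyTable:
    """Per-variant population allele frequencies for the modifier panel."""

    entries: list[FrequencyEntry]
    source_label: str = ""

    @property
    def mafs(self) -> list[float]:
        return [e.maf for e in self.entries]

    def gene_subset(self, gene: str) -> "FrequencyTable":
        return FrequencyTable(
            [e for e in self.entries if e.gene == gene], source_label=self.source_label
        )

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.gene, None)
        return list(seen)


@dataclass
class DigenicRiskEstimate:
    """Bundle of the digenic risk quantities for one panel/mt-variant pair."""

    freq_mt: float
    carrier_freq_nuclear: float
    co_occurrence: float
    predicted_penetrance: float
    predicted_prevalence: float
    expected_cases: float
    population_size: int
    carrier_method: str = "additive"

    def to_dict(self) -> dict:
        return {
            "freq_mt": self.freq_mt,
            "carrier_freq_nuclear": self.carrier_freq_nuclear,
            "co_occurrence": self.co_occurrence,
            "predicted_penetrance": self.predicted_penetrance,
            "predicted_prevalence": self.predicted_prevalence,
            "prevalence_one_in": one_in(self.predicted_prevalence),
            "expected_cases": self.expected_cases,
            "population_size": self.population_size,
            "carrier_method": self.carrier_method,
        }


def _check_fraction(x: float, name: str) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {x}")


def carrier_frequency(mafs: Sequence[float], method: CarrierMethod = "additive") -> float:
    """Probability of carrying >= 1 qualifying allele across independent sites.

    additive
        sum of allele frequencies (clamped to 1) — the cumulative-MAF
        convention used when each frequency is small.
    hardy_weinberg_het
        1 - prod(1 - 2 p_i (1 - p_i)): at least one heterozygous genotype.
    at_least_one_allele
        1 - prod((1 - p_i)^2): at least one allele over the diplotype.
    """
    for p in mafs:
        _check_fraction(p, "maf")
    if len(mafs) == 0:
        return 0.0
    if method == "additive":
        return min(1.0, float(sum(mafs)))
    if method == "hardy_weinberg_het":
        return 1.0 - math.prod(1.0 - 2.0 * p * (1.0 - p) for p in mafs)
    if method == "at_least_one_allele":
        return 1.0 - math.prod((1.0 - p) ** 2 for p in mafs)
    raise ValueError(f"unknown carrier-frequency method {method!r}")


def co_occurrence_probability(freq_mt: float, carrier_freq_nuclear: float) -> float:
    """P(carry mtDNA variant AND a nuclear modifier allele) under independence.

    ``carrier_freq_nuclear`` may be either a carrier frequency or, as in the
    common-modifier workflow, a plain allele frequency — the caller documents
    which was supplied.
    """
    _check_fraction(freq_mt, "freq_mt")
    _check_fraction(carrier_freq_nuclear, "carrier_freq_nuclear")
    return freq_mt * carrier_freq_nuclear


def predicted_penetrance(panel: FrequencyTable, method: CarrierMethod = "additive") -> float:
    """Penetrance among mtDNA carriers = modifier-panel carrier frequency.

    Under the digenic model every mtDNA carrier who also carries >= 1 damaging
    panel allele is affected, so penetrance equals the panel carrier
    frequency; the additive method reproduces the cumulative-MAF convention
    (panel cumulative MAF 0.32 -> 32% of mtDNA carriers affected).
    """
    if not panel.entries:
        raise ValueError("panel frequency table is empty")
    return carrier_frequency(panel.mafs, method)


def predicted_prevalence(carrier_freq_mt: float, penetrance: float) -> float:
    """Disease prevalence = mtDNA carrier frequency x penetrance."""
    _check_fraction(carrier_freq_mt, "carrier_freq_mt")
    _check_fraction(penetrance, "penetrance")
    return carrier_freq_mt * penetrance


def expected_cases(prevalence: float, population_size: int) -> float:
    """Expected case count in a population of the given size."""
    _check_fraction(prevalence, "prevalence")
    if population_size <= 0:
        raise ValueError("population_size must be positive")
    return prevalence * population_size


def maf_from_carrier_counts(
    carriers: int,
    n_individuals: int,
    inheritance: Literal["haploid_mt", "autosomal"] = "haploid_mt",
) -> float:
    """Allele frequency from a carrier count in a biobank-style sample.

    ``haploid_mt``: homoplasmic mtDNA, one allele per individual, MAF =
    carriers / N.  ``autosomal``: ``carriers`` is the allele count over 2N
    chromosomes (heterozygous carriers contribute 1 each).
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    denom = n_individuals if inheritance == "haploid_mt" else 2 * n_individuals
    if not 0 <= carriers <= denom:
        raise ValueError(f"carriers {carriers} outside [0, {denom}] for {inheritance}")
    return carriers / denom


def one_in(prevalence: float, sig_figs: int = 1) -> str:
    """Human-readable '1 in N' rendering, N rounded to ``sig_figs``.

    Exact arithmetic stays upstream; this is a display-layer convenience
    (0 maps to '1 in inf' explicitly).
    """
    if prevalence == 0:
        return "1 in inf"
    _check_fraction(prevalence, "prevalence")
    n = 1.0 / prevalence
    magnitude = math.floor(math.log10(n))
    rounded = round(n, -(magnitude - sig_figs + 1))
    return f"1 in {int(rounded):,}"


def estimate_digenic_risk(
    panel: FrequencyTable,
    freq_mt: float = 1e-4,
    method: CarrierMethod = "additive",
    population_size: int = DEFAULT_POPULATION,
    penetrance_override: float | None = None,
) -> DigenicRiskEstimate:
    """Full digenic risk workflow for a panel and an mtDNA allele frequency.

    ``penetrance_override`` substitutes an externally reported penetrance
    (e.g. the ~30% within-family figure) for the panel-derived one.
    """
    c_nuc = carrier_frequency(panel.mafs, method)
    pen = penetrance_override if penetrance_override is not None else predicted_penetrance(panel, method)
    prev = predicted_prevalence(freq_mt, pen)
    return DigenicRiskEstimate(
        freq_mt=freq_mt,
        carrier_freq_nuclear=c_nuc,
        co_occurrence=co_occurrence_probability(freq_mt, c_nuc),
        predicted_penetrance=pen,
        predicted_prevalence=prev,
        expected_cases=expected_cases(prev, population_size),
        population_size=population_size,
        carrier_method=method,
    )
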
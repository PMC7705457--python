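"""Damaging-variant classification, rarity filtering and segregation partitioning.

The filtering rules mirror standard rare-disease exome triage: loss-of-function
consequence classes (splice-site, frameshift, stop gain/loss) qualify outright,
while missense variants qualify only when a consensus of in-silico predictors
calls them damaging, the site is evolutionarily conserved and it falls in a
known InterPro domain.  Qualifying variants are then restricted to rare alleles
and partitioned by whether their carriers are exclusively affected, exclusively
unaffected, or mixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Iterable, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import Cohort

logger = logging.getLogger(__name__)

MT_CONTIG = "chrM"

#: Default six-gene nuclear modifier panel (mt-tRNA(Glu) interactors).
DEFAULT_PANEL = frozenset({"EARS2", "TRMU", "QRSL1", "GOT2", "GLS", "MSS51"})


class Consequence(str, Enum):
    SPLICE_SITE = "splice_site"
    FRAMESHIFT = "frameshift"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Consequence classes that qualify as potentially pathogenic unconditionally.
LOF_CLASSES = frozenset(
    {Consequence.SPLICE_SITE, Consequence.FRAMESHIFT, Consequence.STOP_GAIN, Consequence.STOP_LOSS}
)


class Genome(str, Enum):
    NUCLEAR = "nuclear"
    MITOCHONDRIAL = "mitochondrial"


@dataclass(frozen=True)
class AnnotatedVariant:
    """One annotated nuclear or mitochondrial variant.

    ``predicted_damaging``/``conserved``/``in_domain`` may be ``None`` for
    consequence classes where they are irrelevant, but must be set for
    missense variants before classification.
    """

    id: str
    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    gene: str
    consequence: Consequence
    predicted_damaging: bool | None = None
    conserved: bool | None = None
    in_domain: bool | None = None
    population_maf: float | None = None
    genome: Genome = Genome.NUCLEAR

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.id}: position must be >= 1 (got {self.position})")
        if self.population_maf is not None and not 0.0 <= self.population_maf <= 1.0:
            raise ValueError(f"{self.id}: population MAF {self.population_maf} outside [0, 1]")
        if self.genome is Genome.MITOCHONDRIAL and self.contig != MT_CONTIG:
            raise ValueError(
                f"{self.id}: mitochondrial variant must be on contig {MT_CONTIG!r}, got {self.contig!r}"
            )


@dataclass(frozen=True)
class FilterConfig:
    """Knobs for the pathogenicity/rarity filter.

    ``maf_threshold`` defaults to 0.005, strictly containing the modifier
    variants of interest (all at MAF < 0.002 in reference databases).
    """

    maf_threshold: float = 0.005
    require_domain: bool = True
    require_conservation: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_threshold <= 1.0:
            raise ValueError(f"maf_threshold must be in (0, 1], got {self.maf_threshold}")


@dataclass(frozen=True)
class Classification:
    """Boolean verdict plus the rule branch that produced it."""

    is_pathogenic: bool
    reason: str

    def __bool__(self) -> bool:
        return self.is_pathogenic


@dataclass
class SegregationPartition:
    """Variant ids split by the affection status of their carriers."""

    affected_only: set[str] = field(default_factory=set)
    unaffected_only: set[str] = field(default_factory=set)
    shared: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        groups = [self.affected_only, self.unaffected_only, self.shared]
        for i, a in enumerate(groups):
            for b in groups[i + 1 :]:
                if a & b:
                    raise ValueError("segregation partition sets must be pairwise disjoint")

    @property
    def all_ids(self) -> set[str]:
        return self.affected_only | self.unaffected_only | self.shared


def classify_potentially_pathogenic(
    variant: AnnotatedVariant, config: FilterConfig | None = None
) -> Classification:
    """Decide whether ``variant`` is potentially pathogenic.

    Loss-of-function classes pass unconditionally.  Missense variants pass iff
    predicted damaging AND (conserved or conservation not required) AND
    (in a known domain or domain membership not required).  All other classes
    (synonymous, other) fail.

    Raises ``ValueError`` if a missense variant is missing any required
    annotation flag — silent false negatives are never produced.
    """
    config = config or FilterConfig()
    if variant.consequence in LOF_CLASSES:
        return Classification(True, f"loss-of-function class: {variant.consequence.value}")
    if variant.consequence is Consequence.MISSENSE:
        missing = [
            name
            for name, value in (
                ("predicted_damaging", variant.predicted_damaging),
                ("conserved", variant.conserved),
                ("in_domain", variant.in_domain),
            )
            if value is None
        ]
        if missing:
            raise ValueError(
                f"{variant.id}: missense variant missing annotation flag(s): {', '.join(missing)}"
            )
        if not variant.predicted_damaging:
            return Classification(False, "missense not predicted damaging")
        if config.require_conservation and not variant.conserved:
            return Classification(False, "missense at non-conserved site")
        if config.require_domain and not variant.in_domain:
            return Classification(False, "missense outside known InterPro domain")
        return Classification(True, "damaging missense (conservation/domain criteria met)")
    return Classification(False, f"excluded consequence class: {variant.consequence.value}")


def apply_rarity_filter(
    variants: Sequence[AnnotatedVariant], config: FilterConfig | None = None
) -> list[AnnotatedVariant]:
    """Keep variants with population MAF strictly below the threshold.

    A missing MAF is treated as 0 (a novel allele passes) with a logged
    warning; a negative MAF is an input error.  Input order is preserved.
    """
    config = config or FilterConfig()
    kept: list[AnnotatedVariant] = []
    for v in variants:
        maf = v.population_maf
        if maf is None:
            logger.warning("%s: missing population MAF treated as 0 (novel allele)", v.id)
            maf = 0.0
        if maf < 0:
            raise ValueError(f"{v.id}: negative population MAF {maf}")
        if maf < config.maf_threshold:
            kept.append(v)
    return kept


def filter_damaging_rare(
    variants: Sequence[AnnotatedVariant], config: FilterConfig | None = None
) -> list[AnnotatedVariant]:
    """Compose the pathogenicity classifier with the rarity filter (idempotent)."""
    config = config or FilterConfig()
    damaging = [v for v in variants if classify_potentially_pathogenic(v, config)]
    return apply_rarity_filter(damaging, config)


def partition_by_segregation(
    cohort: "Cohort", variants: Iterable[AnnotatedVariant | str]
) -> SegregationPartition:
    """Partition variants by whether all carriers are affected or unaffected.

    A variant with every carrier affected goes to ``affected_only``; with every
    carrier unaffected to ``unaffected_only``; otherwise to ``shared``.
    Carriers of unknown affection force the variant to ``shared`` (warned).
    Variants with zero genotyped carriers are dropped and counted in a log line.
    """
    partition = SegregationPartition()
    n_uncarried = 0
    for v in variants:
        vid = v if isinstance(v, str) else v.id
        carriers = cohort.carriers_of(vid)
        if not carriers:
            n_uncarried += 1
            continue
        statuses = {cohort.individual(c).affection for c in carriers}
        from .cohort import Affection  # local import avoids a cycle

        if Affection.UNKNOWN in statuses:
            logger.warning(
                "%s: carrier with unknown affection status; variant forced to shared", vid
            )
            partition.shared.add(vid)
        elif statuses == {Affection.AFFECTED}:
            partition.affected_only.add(vid)
        elif statuses == {Affection.UNAFFECTED}:
            partition.unaffected_only.add(vid)
        else:
            partition.shared.add(vid)
    if n_uncarried:
        logger.info("segregation partition: %d variant(s) with zero carriers excluded", n_uncarried)
    return partition
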
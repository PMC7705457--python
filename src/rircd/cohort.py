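"""Pedigree cohort container: individuals, genotypes and the modifier panel.

A ``Cohort`` couples a list of individuals (with affection status and
homoplasmic mtDNA carrier state) to a sparse genotype table of nuclear
allele counts, plus the set of qualifying (damaging, rare) panel variant
ids over which cumulative allele burdens are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

from .variants import DEFAULT_PANEL

logger = logging.getLogger(__name__)


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class Role(str, Enum):
    FAMILY = "family"       # pedigree member of a study family
    CONTROL = "control"     # population control without pedigree


@dataclass(frozen=True)
class Individual:
    id: str
    family_id: str
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    mt_carrier: bool = False
    mother_id: str | None = None
    father_id: str | None = None
    role: Role = Role.FAMILY


@dataclass
class Cohort:
    """Individuals + genotype calls + the qualifying panel variant set.

    ``genotypes`` maps ``(individual_id, variant_id)`` to an allele count in
    {0, 1, 2}; absent keys mean 0 copies.  ``qualifying_variants`` holds the
    ids of damaging-rare variants in panel genes that enter burden counts.
    """

    individuals: list[Individual]
    genotypes: dict[tuple[str, str], int] = field(default_factory=dict)
    panel: frozenset[str] = DEFAULT_PANEL
    qualifying_variants: set[str] = field(default_factory=set)
    variant_genes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {ind.id for ind in self.individuals}
        if len(ids) != len(self.individuals):
            raise ValueError("duplicate individual ids in cohort")
        self._by_id = {ind.id: ind for ind in self.individuals}
        for (iid, _vid), count in self.genotypes.items():
            if iid not in ids:
                raise ValueError(f"genotype references unknown individual {iid!r}")
            if count not in (0, 1, 2):
                raise ValueError(f"allele count must be 0/1/2, got {count} for {iid!r}")
        self._check_maternal_consistency()

    def _check_maternal_consistency(self) -> None:
        # Homoplasmic mtDNA is maternally transmitted: children of a carrier
        # mother should be carriers.  Inconsistencies are warned, not fatal.
        for ind in self.individuals:
            if ind.mother_id and ind.mother_id in self._by_id:
                mother = self._by_id[ind.mother_id]
                if mother.mt_carrier != ind.mt_carrier:
                    logger.warning(
                        "maternal mtDNA inconsistency: %s (carrier=%s) child of %s (carrier=%s)",
                        ind.id, ind.mt_carrier, mother.id, mother.mt_carrier,
                    )

    def individual(self, individual_id: str) -> Individual:
        return self._by_id[individual_id]

    @property
    def individual_ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def allele_count(self, individual_id: str, variant_id: str) -> int:
        return self.genotypes.get((individual_id, variant_id), 0)

    def carriers_of(self, variant_id: str) -> list[str]:
        """Individuals with >= 1 copy of ``variant_id``, in cohort order."""
        return [
            ind.id for ind in self.individuals
            if self.genotypes.get((ind.id, variant_id), 0) > 0
        ]

    def variants_of(self, individual_id: str) -> dict[str, int]:
        """Nonzero genotype calls for one individual."""
        return {
            vid: count
            for (iid, vid), count in self.genotypes.items()
            if iid == individual_id and count > 0
        }
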
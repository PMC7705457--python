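"""Readers and writers for the dialects the analysis consumes.

Variants: minimal VCF 4.x (INFO keys GENE, CSQCLS, DMG, CONS, DOM, MAF, via
pysam) or a TSV with the same column names.  Pedigrees: 6-column PED
(family, individual, father, mother, sex, affection 1/2/0) plus a genotype
TSV (individual_id, variant_id, allele_count).  Frequency tables: TSV
(gene, variant_id, maf) or YAML.  Coordinates are 1-based throughout.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam
import yaml

from .cohort import Affection, Cohort, Individual, Role, Sex
from .digenic import FrequencyEntry, FrequencyTable
from .variants import MT_CONTIG, AnnotatedVariant, Consequence, Genome

_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_AFF_CODES = {"1": Affection.UNAFFECTED, "2": Affection.AFFECTED, "0": Affection.UNKNOWN}

VARIANT_COLUMNS = [
    "id", "contig", "position", "ref_allele", "alt_allele",
    "GENE", "CSQCLS", "DMG", "CONS", "DOM", "MAF",
]


def _to_bool(x) -> bool | None:
    if x is None or (isinstance(x, float) and pd.isna(x)) or x == ".":
        return None
    if isinstance(x, bool):
        return x
    return str(x).strip().lower() in {"1", "true", "t", "yes"}


def _variant_from_fields(
    vid, contig, pos, ref, alt, gene, csqcls, dmg, cons, dom, maf
) -> AnnotatedVariant:
    genome = Genome.MITOCHONDRIAL if contig == MT_CONTIG else Genome.NUCLEAR
    return AnnotatedVariant(
        id=str(vid), contig=str(contig), position=int(pos),
        ref_allele=str(ref), alt_allele=str(alt), gene=str(gene),
        consequence=Consequence(str(csqcls)),
        predicted_damaging=_to_bool(dmg), conserved=_to_bool(cons), in_domain=_to_bool(dom),
        population_maf=None if maf is None or (isinstance(maf, float) and pd.isna(maf)) else float(maf),
        genome=genome,
    )


def read_variants_tsv(path: str | Path) -> list[AnnotatedVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "contig": str})
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing column(s): {sorted(missing)}")
    return [
        _variant_from_fields(
            r.id, r.contig, r.position, r.ref_allele, r.alt_allele,
            r.GENE, r.CSQCLS, r.DMG, r.CONS, r.DOM, r.MAF,
        )
        for r in df.itertuples(index=False)
    ]


def write_variants_tsv(variants: Iterable[AnnotatedVariant], path: str | Path) -> None:
    rows = [
        {
            "id": v.id, "contig": v.contig, "position": v.position,
            "ref_allele": v.ref_allele, "alt_allele": v.alt_allele,
            "GENE": v.gene, "CSQCLS": v.consequence.value,
            "DMG": v.predicted_damaging, "CONS": v.conserved, "DOM": v.in_domain,
            "MAF": v.population_maf,
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants_vcf(path: str | Path) -> list[AnnotatedVariant]:
    """Minimal VCF 4.x reader: one ALT per record, annotations in INFO."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"{rec.id or rec.pos}: expected exactly one ALT allele")
            info = rec.info
            out.append(
                _variant_from_fields(
                    rec.id or f"{rec.chrom}_{rec.pos}_{rec.ref}_{rec.alts[0]}",
                    rec.chrom, rec.pos, rec.ref, rec.alts[0],
                    info["GENE"], info["CSQCLS"],
                    info.get("DMG"), info.get("CONS"), info.get("DOM"), info.get("MAF"),
                )
            )
    return out


def write_variants_vcf(variants: Iterable[AnnotatedVariant], path: str | Path) -> None:
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    contigs = sorted({v.contig for v in variants})
    for c in contigs:
        header.contigs.add(c)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("CSQCLS", 1, "String", "Consequence class")
    header.info.add("DMG", 0, "Flag", "Consensus damaging prediction")
    header.info.add("CONS", 0, "Flag", "Evolutionary conservation")
    header.info.add("DOM", 0, "Flag", "In known InterPro domain")
    header.info.add("MAF", 1, "Float", "Population minor allele frequency")
    variants = list(variants)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in variants:
            rec = vcf.new_record(
                contig=v.contig, start=v.position - 1, stop=v.position,
                alleles=(v.ref_allele, v.alt_allele), id=v.id,
            )
            rec.info["GENE"] = v.gene
            rec.info["CSQCLS"] = v.consequence.value
            if v.predicted_damaging:
                rec.info["DMG"] = True
            if v.conserved:
                rec.info["CONS"] = True
            if v.in_domain:
                rec.info["DOM"] = True
            if v.population_maf is not None:
                rec.info["MAF"] = v.population_maf
            vcf.write(rec)


def read_ped(path: str | Path, mt_carriers: set[str] | None = None) -> list[Individual]:
    """6-column PED: family, individual, father, mother, sex, affection.

    ``mt_carriers`` optionally marks the homoplasmic mtDNA carriers (PED has
    no mtDNA column); '0' parent codes mean founder.
    """
    mt_carriers = mt_carriers or set()
    individuals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"PED line has {len(fields)} fields, expected 6: {line!r}")
            fam, iid, father, mother, sex, aff = fields[:6]
            individuals.append(
                Individual(
                    id=iid, family_id=fam,
                    sex=_SEX_CODES.get(sex, Sex.UNKNOWN),
                    affection=_AFF_CODES.get(aff, Affection.UNKNOWN),
                    mt_carrier=iid in mt_carriers,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                )
            )
    return individuals


def write_ped(individuals: Iterable[Individual], path: str | Path) -> None:
    sex_rev = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    aff_rev = {Affection.UNAFFECTED: "1", Affection.AFFECTED: "2", Affection.UNKNOWN: "0"}
    with open(path, "w") as fh:
        for ind in individuals:
            fh.write(
                " ".join(
                    [
                        ind.family_id, ind.id, ind.father_id or "0", ind.mother_id or "0",
                        sex_rev[ind.sex], aff_rev[ind.affection],
                    ]
                )
                + "\n"
            )


def read_genotypes_tsv(path: str | Path) -> dict[tuple[str, str], int]:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "variant_id": str})
    required = {"individual_id", "variant_id", "allele_count"}
    if not required <= set(df.columns):
        raise ValueError(f"genotype TSV missing column(s): {sorted(required - set(df.columns))}")
    return {
        (r.individual_id, r.variant_id): int(r.allele_count) for r in df.itertuples(index=False)
    }


def write_genotypes_tsv(genotypes: dict[tuple[str, str], int], path: str | Path) -> None:
    rows = [
        {"individual_id": iid, "variant_id": vid, "allele_count": count}
        for (iid, vid), count in sorted(genotypes.items())
    ]
    pd.DataFrame(rows, columns=["individual_id", "variant_id", "allele_count"]).to_csv(
        path, sep="\t", index=False
    )


def load_cohort(
    ped_path: str | Path,
    genotypes_path: str | Path,
    mt_carriers: set[str] | None = None,
    qualifying_variants: set[str] | None = None,
) -> Cohort:
    individuals = read_ped(ped_path, mt_carriers=mt_carriers)
    genotypes = read_genotypes_tsv(genotypes_path)
    quals = qualifying_variants if qualifying_variants is not None else {
        vid for (_iid, vid) in genotypes
    }
    return Cohort(individuals=individuals, genotypes=genotypes, qualifying_variants=quals)


def read_frequency_table(path: str | Path) -> FrequencyTable:
    """TSV (gene, variant_id, maf) or YAML with entries: [{gene, variant_id, maf}]."""
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        data = yaml.safe_load(path.read_text())
        entries = [
            FrequencyEntry(e["gene"], e["variant_id"], float(e["maf"])) for e in data["entries"]
        ]
        return FrequencyTable(entries, source_label=data.get("source_label", str(path)))
    df = pd.read_csv(path, sep="\t")
    return FrequencyTable(
        [FrequencyEntry(str(r.gene), str(r.variant_id), float(r.maf))
         for r in df.itertuples(index=False)],
        source_label=str(path),
    )


def write_frequency_table(table: FrequencyTable, path: str | Path) -> None:
    pd.DataFrame(
        [{"gene": e.gene, "variant_id": e.variant_id, "maf": e.maf} for e in table.entries]
    ).to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "metric"} <= set(df.columns):
        raise ValueError("expression TSV needs columns: gene, metric")
    return df


def read_ct_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "ct_b2m", "ct_mtnd1"}
    if not required <= set(df.columns):
        raise ValueError(f"Ct TSV missing column(s): {sorted(required - set(df.columns))}")
    return df


def read_protein_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "log2_ratio", "anova_p", "unique_peptides", "quantified_in_all"}
    if not required <= set(df.columns):
        raise ValueError(f"protein TSV missing column(s): {sorted(required - set(df.columns))}")
    return df
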
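#!/usr/bin/env python
"""Classify damaging-rare variants and partition them by segregation with
affection status in the simulated pedigrees.

Finding to expect: only the rare variants (MAF < 0.005) survive the filter —
the common TRMU-like allele (0.097) must be handled outside the rare-variant
channel — but at this cohort size most rare alleles have no carriers at all,
so the rare-variant partition is typically empty, while the common panel
alleles are carried by affected and unaffected members alike and land in
'shared'.  Exclusive segregation is a property of the observed family
variants, not of the population-frequency panel.
"""

import argparse
import json
from pathlib import Path

from rircd import FilterConfig, filter_damaging_rare, partition_by_segregation
from rircd.io import load_cohort, read_variants_tsv

parser = argparse.ArgumentParser()
parser.add_argument("--indir", type=Path, default=Path("results/simulated"))
parser.add_argument("--out", type=Path, default=Path("results/filtering.json"))
parser.add_argument("--maf-threshold", type=float, default=0.005)
args = parser.parse_args()

variants = read_variants_tsv(args.indir / "variants.tsv")
carriers = set((args.indir / "mt_carriers.txt").read_text().split())
cohort = load_cohort(args.indir / "cohort.ped", args.indir / "genotypes.tsv",
                     mt_carriers=carriers)

config = FilterConfig(maf_threshold=args.maf_threshold)
kept = filter_damaging_rare(variants, config)
partition = partition_by_segregation(cohort, kept)
# rare variants are often absent from a cohort this size; partition the whole
# damaging set too, so the common modifier alleles show their carrier pattern
damaging_all = [v for v in variants if v.consequence.value != "other"]
partition_all = partition_by_segregation(cohort, damaging_all)

result = {
    "n_input": len(variants),
    "n_damaging_rare": len(kept),
    "kept": [v.id for v in kept],
    "rare": {
        "affected_only": sorted(partition.affected_only),
        "unaffected_only": sorted(partition.unaffected_only),
        "shared": sorted(partition.shared),
    },
    "all_damaging": {
        "affected_only": sorted(partition_all.affected_only),
        "unaffected_only": sorted(partition_all.unaffected_only),
        "shared": sorted(partition_all.shared),
    },
}
args.out.parent.mkdir(parents=True, exist_ok=True)
args.out.write_text(json.dumps(result, indent=2) + "\n")
print(f"{result['n_damaging_rare']}/{result['n_input']} variants damaging & rare "
      f"(threshold {args.maf_threshold})")
for label, part in (("rare", result["rare"]), ("all damaging", result["all_damaging"])):
    print(f"segregation ({label}): {len(part['affected_only'])} affected-only, "
          f"{len(part['unaffected_only'])} unaffected-only, {len(part['shared'])} shared")
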
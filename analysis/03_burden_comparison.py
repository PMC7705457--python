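#!/usr/bin/env python
"""Cumulative damaging-allele burden: affected vs unaffected carriers vs
population controls, plus null calibration of the test.

Finding to expect: affected carriers average about one allele more than
unaffected carriers (the extra nuclear modifier hit on top of the shared
homoplasmic mtDNA allele), and the affected-vs-control separation is larger
still; the type-I error of the pooled t at the study's group sizes (22 vs 12)
stays near the nominal 5%.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from rircd import SimulationConfig, burden_table, compare_groups, simulate_burden_power
from rircd.cohort import Cohort, Individual, Affection, Role
from rircd.io import load_cohort, read_genotypes_tsv

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--indir", type=Path, default=Path("results/simulated"))
parser.add_argument("--out", type=Path, default=Path("results/burden.json"))
args = parser.parse_args()

carriers = set((args.indir / "mt_carriers.txt").read_text().split())
cohort = load_cohort(args.indir / "cohort.ped", args.indir / "genotypes.tsv",
                     mt_carriers=carriers)
control_gts = read_genotypes_tsv(args.indir / "control_genotypes.tsv")
control_ids = sorted({iid for iid, _ in control_gts})
controls = [
    Individual(id=i, family_id="controls", affection=Affection.UNAFFECTED,
               role=Role.CONTROL)
    for i in control_ids
]
# controls without any panel allele never appear in the genotype TSV
n_controls = SimulationConfig(seed=args.seed).n_controls
absent = [
    Individual(id=f"CTRL{k + 1}", family_id="controls", affection=Affection.UNAFFECTED,
               role=Role.CONTROL)
    for k in range(n_controls)
    if f"CTRL{k + 1}" not in set(control_ids)
]
full = Cohort(
    individuals=cohort.individuals + controls + absent,
    genotypes={**cohort.genotypes, **control_gts},
    qualifying_variants=set(cohort.qualifying_variants),
)

table = burden_table(full)
keep = carriers | {i.id for i in controls + absent}
table = table[table["individual_id"].isin(keep)]
table.to_csv(args.out.parent / "burden_table.tsv", sep="\t", index=False)

cmp_unaff = compare_groups(table, "affected", "unaffected", seed=args.seed)
cmp_ctrl = compare_groups(table, "affected", "control", seed=args.seed)
freqs = [e.maf for e in SimulationConfig(seed=args.seed).panel.entries]
null = simulate_burden_power(freqs, group_sizes=(22, 12), effect_size=0.0,
                             n_sims=1000, seed=args.seed)

result = {
    "affected_vs_unaffected": cmp_unaff.to_dict(),
    "affected_vs_control": cmp_ctrl.to_dict(),
    "null_type1": null,
}
args.out.parent.mkdir(parents=True, exist_ok=True)
args.out.write_text(json.dumps(result, indent=2) + "\n")

m = cmp_unaff.group_means
print(f"affected vs unaffected carriers: {m[0]:.2f} vs {m[1]:.2f} alleles, "
      f"t = {cmp_unaff.t_statistic:.2f}, p = {cmp_unaff.p_value:.2g}")
m = cmp_ctrl.group_means
print(f"affected vs controls: {m[0]:.2f} vs {m[1]:.2f} alleles, "
      f"t = {cmp_ctrl.t_statistic:.2f}, p = {cmp_ctrl.p_value:.2g}")
print(f"null rejection rate at alpha=0.05: {null['power']:.3f} "
      f"(+/- {null['mc_se']:.3f}, {null['n_sims']} sims)")
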
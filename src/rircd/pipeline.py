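"""End-to-end orchestration: simulate -> filter -> burden -> digenic,
plus the independent composition and assay stages, with a combined report.

Every numeric in the markdown report is read back from the stage JSON, the
seed and a config hash are recorded in every output, and reruns with the same
config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assays import (
    QpcrSample,
    flag_regulated,
    protein_table_to_ratios,
    regulation_thresholds,
    summarize_copy_number,
)
from .burden import burden_table, compare_groups
from .cohort import Cohort
from .composition import composition_frame, composition_table, correlate_composition_expression
from .digenic import DEFAULT_POPULATION, estimate_digenic_risk, co_occurrence_probability
from .synthetic import (
    SimulationConfig,
    control_individuals,
    simulate_assay_tables,
    simulate_cohort,
    simulate_control_genotypes,
    simulate_expression,
)
from .variants import FilterConfig, filter_damaging_rare, partition_by_segregation

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "burden", "digenic", "composition", "assays")


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str | Path = "results"
    stages: tuple[str, ...] = STAGES
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    burden_method: str = "student_t"
    n_perm: int = 10_000
    freq_mt: float = 1e-4
    population_size: int = DEFAULT_POPULATION
    penetrance_override: float | None = 0.30
    carrier_method: str = "additive"
    trmu_allele_freq: float = 0.09695
    expression_slope: float = -30.0
    expression_noise: float = 0.4
    sim: SimulationConfig | None = None

    def simulation(self) -> SimulationConfig:
        return self.sim or SimulationConfig(seed=self.seed)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all requested stages in dependency order; return the report bundle.

    Outputs under ``config.output_dir``: per-stage JSON, burden table TSV,
    composition scatter TSV, a markdown summary and a MANIFEST listing stage
    status.  Partial results are kept if a stage fails.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation()
    meta = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }
    report: dict = {"meta": meta}
    manifest: dict[str, str] = {}

    cohort: Cohort | None = None
    variant_records = None

    def stage_enabled(name: str) -> bool:
        return name in config.stages

    try:
        if stage_enabled("simulate"):
            cohort, variant_records, truth = simulate_cohort(sim)
            controls = simulate_control_genotypes(sim)
            ctrl_inds = control_individuals(sim)
            full = Cohort(
                individuals=cohort.individuals + ctrl_inds,
                genotypes={
                    **cohort.genotypes,
                    **{
                        (r.individual_id, r.variant_id): int(r.allele_count)
                        for r in controls.itertuples(index=False)
                    },
                },
                qualifying_variants=set(cohort.qualifying_variants),
                variant_genes=dict(cohort.variant_genes),
            )
            cohort = full
            report["simulate"] = {
                "n_individuals": len(cohort.individuals),
                "n_families": sim.n_families,
                "n_controls": sim.n_controls,
                "n_panel_variants": len(sim.panel.entries),
                "n_affected_truth": int(truth["affected"].sum()),
            }
            manifest["simulate"] = "ok"

        if stage_enabled("filter"):
            if variant_records is None:
                raise RuntimeError("filter stage requires the simulate stage")
            damaging_rare = filter_damaging_rare(variant_records, config.filter_config)
            partition = partition_by_segregation(cohort, damaging_rare)
            report["filter"] = {
                "n_input": len(variant_records),
                "n_damaging_rare": len(damaging_rare),
                "affected_only": sorted(partition.affected_only),
                "unaffected_only": sorted(partition.unaffected_only),
                "shared": sorted(partition.shared),
            }
            manifest["filter"] = "ok"

        if stage_enabled("burden"):
            if cohort is None:
                raise RuntimeError("burden stage requires the simulate stage")
            table = burden_table(cohort)
            # the affected/unaffected contrast is among mtDNA carriers, as in
            # a homoplasmic-family design; controls enter as their own group
            carrier_ids = {
                ind.id for ind in cohort.individuals if ind.mt_carrier or ind.role.value == "control"
            }
            table = table[table["individual_id"].isin(carrier_ids)]
            table.to_csv(outdir / "burden_table.tsv", sep="\t", index=False)
            cmp_aff_unaff = compare_groups(
                table, "affected", "unaffected", method=config.burden_method,
                n_perm=config.n_perm, seed=config.seed,
            )
            cmp_aff_ctrl = compare_groups(
                table, "affected", "control", method=config.burden_method,
                n_perm=config.n_perm, seed=config.seed,
            )
            report["burden"] = {
                "affected_vs_unaffected": cmp_aff_unaff.to_dict(),
                "affected_vs_control": cmp_aff_ctrl.to_dict(),
            }
            manifest["burden"] = "ok"

        if stage_enabled("digenic"):
            panel = sim.panel
            est = estimate_digenic_risk(
                panel,
                freq_mt=config.freq_mt,
                method=config.carrier_method,
                population_size=config.population_size,
                penetrance_override=config.penetrance_override,
            )
            ears2 = panel.gene_subset("EARS2")
            report["digenic"] = {
                "estimate": est.to_dict(),
                "co_occurrence_mt_ears2": co_occurrence_probability(
                    config.freq_mt, sum(ears2.mafs)
                ),
                "co_occurrence_mt_trmu_common": co_occurrence_probability(
                    config.freq_mt, config.trmu_allele_freq
                ),
                "panel_cumulative_maf": sum(panel.mafs),
            }
            manifest["digenic"] = "ok"

        if stage_enabled("composition"):
            comp = composition_table()
            expr = simulate_expression(
                comp, slope=config.expression_slope, noise=config.expression_noise,
                seed=config.seed,
            )
            corr = correlate_composition_expression(comp, expr)
            scatter = composition_frame(comp).merge(expr, on="gene")
            scatter.to_csv(outdir / "composition_scatter.tsv", sep="\t", index=False)
            top = max(comp, key=lambda r: r.count_EQ)
            report["composition"] = {
                "n_proteins": len(comp),
                "correlation": corr.to_dict(),
                "max_EQ_gene": top.gene,
                "max_EQ_count": top.count_EQ,
            }
            manifest["composition"] = "ok"

        if stage_enabled("assays"):
            ct_table, protein_table = simulate_assay_tables(sim)
            groups: dict[str, list[QpcrSample]] = {}
            for r in ct_table.itertuples(index=False):
                groups.setdefault(r.group, []).append(
                    QpcrSample(
                        sample_id=r.sample_id, ct_nuclear=r.ct_b2m, ct_mt=r.ct_mtnd1,
                        replicate_id=r.replicate_id,
                    )
                )
            copy_summary = summarize_copy_number(groups)
            ratios = protein_table_to_ratios(protein_table)
            thresholds = regulation_thresholds(ratios)
            regulated = flag_regulated(ratios, thresholds)
            report["assays"] = {
                "copy_number": copy_summary,
                "thresholds": {
                    "mean_log2": thresholds.mean_log2,
                    "sd_log2": thresholds.sd_log2,
                    "lower": thresholds.lower,
                    "upper": thresholds.upper,
                },
                "n_down": len(regulated["down"]),
                "n_up": len(regulated["up"]),
                "n_unchanged": len(regulated["unchanged"]),
            }
            manifest["assays"] = "ok"
    except Exception as exc:  # record the failed stage, keep partial outputs
        failed = next((s for s in config.stages if s not in manifest), "unknown")
        manifest[failed] = f"failed: {exc}"
        _write_json(outdir / "MANIFEST.json", manifest)
        raise

    _write_json(outdir / "report.json", report)
    _write_json(outdir / "MANIFEST.json", manifest)
    (outdir / "report.md").write_text(render_markdown_report(report))
    return report


def render_markdown_report(report: dict) -> str:
    """Markdown summary; every number is read from the report dict."""
    lines = ["# Digenic mtDNA-nuclear modifier analysis report", ""]
    meta = report["meta"]
    lines += [
        f"- version: {meta['version']}",
        f"- seed: {meta['seed']}",
        f"- config hash: {meta['config_hash']}",
        "",
    ]
    if "simulate" in report:
        s = report["simulate"]
        lines += [
            "## Simulated cohort",
            f"- {s['n_families']} families, {s['n_individuals']} individuals "
            f"(incl. {s['n_controls']} population controls)",
            f"- {s['n_panel_variants']} panel variants; {s['n_affected_truth']} affected (truth)",
            "",
        ]
    if "filter" in report:
        f = report["filter"]
        lines += [
            "## Variant filtering & segregation",
            f"- {f['n_damaging_rare']} / {f['n_input']} variants damaging and rare",
            f"- affected-only: {len(f['affected_only'])}, unaffected-only: "
            f"{len(f['unaffected_only'])}, shared: {len(f['shared'])}",
            "",
        ]
    if "burden" in report:
        b = report["burden"]["affected_vs_unaffected"]
        c = report["burden"]["affected_vs_control"]
        lines += [
            "## Allele burden",
            f"- affected vs unaffected carriers: means {b['group_means'][0]:.2f} vs "
            f"{b['group_means'][1]:.2f}, t = {b['t_statistic']:.2f}, p = {b['p_value']:.2g}",
            f"- affected vs controls: means {c['group_means'][0]:.2f} vs "
            f"{c['group_means'][1]:.2f}, t = {c['t_statistic']:.2f}, p = {c['p_value']:.2g}",
            "",
        ]
    if "digenic" in report:
        d = report["digenic"]
        e = d["estimate"]
        lines += [
            "## Digenic risk arithmetic",
            f"- P(mt variant AND EARS2 modifier) = {d['co_occurrence_mt_ears2']:.3g}",
            f"- P(mt variant AND common TRMU modifier) = {d['co_occurrence_mt_trmu_common']:.3g}",
            f"- panel cumulative MAF = {d['panel_cumulative_maf']:.3g} "
            f"(predicted penetrance among carriers)",
            f"- predicted prevalence = {e['predicted_prevalence']:.3g} "
            f"({e['prevalence_one_in']}), expected cases = {e['expected_cases']:.0f} "
            f"in a population of {e['population_size']:,}",
            "",
        ]
    if "composition" in report:
        comp = report["composition"]
        corr = comp["correlation"]
        lines += [
            "## Glu+Gln composition vs expression change",
            f"- {comp['n_proteins']} proteins; {corr['method']} r = {corr['r']:.3f}, "
            f"p = {corr['p_value']:.3g} (n = {corr['n']})",
            f"- highest absolute E+Q count: {comp['max_EQ_gene']} ({comp['max_EQ_count']})",
            "",
        ]
    if "assays" in report:
        a = report["assays"]
        th = a["thresholds"]
        fc = a["copy_number"]["fold_changes"]
        fc_str = ", ".join(f"{k}: {v:.2f}" for k, v in fc.items())
        lines += [
            "## Assay models",
            f"- copy-number fold changes: {fc_str}",
            f"- regulation thresholds: [{th['lower']:.2f}, {th['upper']:.2f}] "
            f"(mean {th['mean_log2']:.2f}, SD {th['sd_log2']:.2f})",
            f"- regulated proteins: {a['n_down']} down, {a['n_up']} up, "
            f"{a['n_unchanged']} unchanged",
            "",
        ]
    return "\n".join(lines)
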
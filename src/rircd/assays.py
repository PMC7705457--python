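"""Quantitative assay computations: qPCR mtDNA copy number and proteome ratios.

Copy number uses relative quantification against a single-copy nuclear
reference: dCt = Ct(nuclear) - Ct(mt target), copies per diploid cell =
2 * 2^dCt (the factor 2 accounts for the two nuclear reference alleles).
Proteome regulation calls threshold per-protein mean log2 ratios at
mean +/- 2 SD of the full ratio distribution, gated by ANOVA significance
and unique-peptide quantification in all replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import NormalDist
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QpcrSample:
    """One qPCR measurement: nuclear reference Ct (B2M-like) and mt target Ct
    (MT-ND1-like)."""

    sample_id: str
    ct_nuclear: float
    ct_mt: float
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        for name, ct in (("ct_nuclear", self.ct_nuclear), ("ct_mt", self.ct_mt)):
            if ct is None or np.isnan(ct):
                raise ValueError(f"{self.sample_id}: missing {name}")
            if not 0.0 < ct < 45.0:
                logger.warning("%s: %s=%.2f outside plausible cycler range (0, 45)",
                               self.sample_id, name, ct)

    @property
    def delta_ct(self) -> float:
        return self.ct_nuclear - self.ct_mt


@dataclass(frozen=True)
class ProteinRatio:
    protein_id: str
    log2_ratio: float
    anova_p: float
    unique_peptides: bool = True
    quantified_in_all: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.anova_p <= 1.0:
            raise ValueError(f"{self.protein_id}: ANOVA p {self.anova_p} outside [0, 1]")


@dataclass(frozen=True)
class RegulationThresholds:
    mean_log2: float
    sd_log2: float

    @property
    def lower(self) -> float:
        return self.mean_log2 - 2.0 * self.sd_log2

    @property
    def upper(self) -> float:
        return self.mean_log2 + 2.0 * self.sd_log2


def mtdna_copy_number(sample: QpcrSample) -> float:
    """mtDNA copies per diploid cell: 2 * 2^(Ct_nuclear - Ct_mt)."""
    return 2.0 * 2.0 ** sample.delta_ct


def summarize_copy_number(
    groups: dict[str, Sequence[QpcrSample]],
    replicate_averaging: Literal["delta_ct", "copy_number"] = "delta_ct",
) -> dict:
    """Per-group copy-number mean +/- SD and pairwise fold changes.

    Replicates are averaged at the dCt level by default (geometric-mean-like
    on the copy scale, matching the exponential chemistry); per-replicate copy
    numbers then arithmetic mean is available by flag.  The averaging order is
    recorded in the output metadata.
    """
    if not groups or any(len(v) == 0 for v in groups.values()):
        raise ValueError("every group needs >= 1 sample")
    summaries: dict[str, dict] = {}
    for name, samples in groups.items():
        if replicate_averaging == "delta_ct":
            per_sample: dict[str, list[float]] = {}
            for s in samples:
                per_sample.setdefault(s.sample_id, []).append(s.delta_ct)
            copies = np.array(
                [2.0 * 2.0 ** float(np.mean(dcts)) for dcts in per_sample.values()]
            )
        else:
            per_sample = {}
            for s in samples:
                per_sample.setdefault(s.sample_id, []).append(mtdna_copy_number(s))
            copies = np.array([float(np.mean(c)) for c in per_sample.values()])
        summaries[name] = {
            "n": len(copies),
            "mean": float(copies.mean()),
            "sd": float(copies.std(ddof=1)) if len(copies) > 1 else 0.0,
        }
    fold_changes: dict[str, float] = {}
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if summaries[b]["mean"] == 0:
                raise ValueError(f"zero mean copy number in group {b!r}")
            fold_changes[f"{a}_vs_{b}"] = summaries[a]["mean"] / summaries[b]["mean"]
    return {
        "groups": summaries,
        "fold_changes": fold_changes,
        "replicate_averaging": replicate_averaging,
    }


def regulation_thresholds(
    ratios: Sequence[ProteinRatio],
    robust: bool = False,
) -> RegulationThresholds:
    """Regulation cutoffs at mean +/- 2 SD of all quantified log2 ratios.

    SD uses the n-1 denominator.  ``robust=True`` swaps in median and
    1.4826*MAD.  A zero SD yields degenerate (equal) thresholds with a
    warning rather than an error.
    """
    if len(ratios) < 3:
        raise ValueError("need >= 3 protein ratios to estimate thresholds")
    values = np.array([r.log2_ratio for r in ratios], dtype=float)
    if robust:
        center = float(np.median(values))
        spread = 1.4826 * float(np.median(np.abs(values - center)))
    else:
        center = float(values.mean())
        spread = float(values.std(ddof=1))
    if spread == 0:
        logger.warning("zero spread in log2 ratios; degenerate thresholds returned")
    return RegulationThresholds(mean_log2=center, sd_log2=spread)


def flag_regulated(
    ratios: Sequence[ProteinRatio],
    thresholds: RegulationThresholds,
    alpha: float = 0.05,
) -> dict[str, list[str]]:
    """Partition proteins into down / up / unchanged.

    Down: log2 ratio below the lower cutoff AND ANOVA p <= alpha AND unique
    peptides AND quantified in all replicates; up is symmetric above the
    upper cutoff; everything else is unchanged.  Exhaustive and disjoint.
    """
    down, up, unchanged = [], [], []
    for r in ratios:
        qualifies = r.anova_p <= alpha and r.unique_peptides and r.quantified_in_all
        if qualifies and r.log2_ratio < thresholds.lower:
            down.append(r.protein_id)
        elif qualifies and r.log2_ratio > thresholds.upper:
            up.append(r.protein_id)
        else:
            unchanged.append(r.protein_id)
    return {"down": down, "up": up, "unchanged": unchanged}


def expected_false_regulated_rate(alpha: float = 0.05) -> float:
    """Expected fraction flagged under a pure normal null: two-sided 2-SD tail
    times the ANOVA significance rate (independence of the two gates)."""
    tail = 2.0 * (1.0 - NormalDist().cdf(2.0))
    return tail * alpha


def protein_table_to_ratios(table: pd.DataFrame) -> list[ProteinRatio]:
    """Build ProteinRatio records from a TSV-style DataFrame with columns
    protein_id, log2_ratio, anova_p, unique_peptides, quantified_in_all."""
    return [
        ProteinRatio(
            protein_id=str(row.protein_id),
            log2_ratio=float(row.log2_ratio),
            anova_p=float(row.anova_p),
            unique_peptides=bool(row.unique_peptides),
            quantified_in_all=bool(row.quantified_in_all),
        )
        for row in table.itertuples(index=False)
    ]
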
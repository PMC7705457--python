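"""Amino-acid composition of mtDNA-encoded proteins vs expression change.

Counts glutamic acid (E) and glutamine (Q) residues per protein — the two
residues whose tRNA charging/modification the nuclear modifier genes act on —
and correlates the E+Q content with per-gene expression change (default
Pearson, two-sided p from the t distribution with n-2 df).
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Packaged FASTA of the 13 mtDNA-encoded protein sequences.  This fixture is
#: synthetic (see its header and :mod:`rircd.synthetic`): realistic lengths and
#: Glu+Gln compositions, not the reference translations.
DEFAULT_FASTA = "mt13_synthetic.faa"


@dataclass(frozen=True)
class CompositionRecord:
    gene: str
    length: int
    count_E: int
    count_Q: int

    @property
    def count_EQ(self) -> int:
        return self.count_E + self.count_Q

    @property
    def fraction_EQ(self) -> float:
        return self.count_EQ / self.length


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    method: str

    def to_dict(self) -> dict:
        return {"r": self.r, "p_value": self.p_value, "n": self.n, "method": self.method}


def residue_composition(
    sequence: str, gene: str = "", target_residues: frozenset[str] = frozenset("EQ")
) -> CompositionRecord:
    """Exact residue counts for one protein sequence.

    Lowercase input is normalised; a trailing stop ``*`` is tolerated; any
    other non-amino-acid character or an empty sequence is an error.
    """
    seq = sequence.strip().upper().rstrip("*")
    if not seq:
        raise ValueError(f"{gene or 'sequence'}: empty protein sequence")
    unknown = set(seq) - AMINO_ACIDS
    if unknown:
        raise ValueError(f"{gene or 'sequence'}: unknown residue code(s) {sorted(unknown)}")
    if target_residues != frozenset("EQ"):
        # generic counting supported, but the record stores E/Q slots
        raise ValueError("only the E/Q residue set is supported by CompositionRecord")
    return CompositionRecord(
        gene=gene, length=len(seq), count_E=seq.count("E"), count_Q=seq.count("Q")
    )


def composition_table(fasta_path: str | Path | None = None) -> list[CompositionRecord]:
    """Per-protein composition records from a FASTA, ordered by gene name.

    With no path, the packaged 13-protein fixture is used.  Duplicate gene
    names are an error; a record count other than 13 only warns (partial
    panels are legal inputs).
    """
    if fasta_path is None:
        ref = importlib.resources.files("rircd.data").joinpath(DEFAULT_FASTA)
        with importlib.resources.as_file(ref) as p:
            records = list(SeqIO.parse(str(p), "fasta"))
    else:
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 13:
        logger.warning("expected 13 mtDNA-encoded proteins, found %d", len(records))
    genes = [r.id for r in records]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene names in FASTA")
    table = [residue_composition(str(r.seq), gene=r.id) for r in records]
    return sorted(table, key=lambda rec: rec.gene)


def composition_frame(records: list[CompositionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "length": [r.length for r in records],
            "count_E": [r.count_E for r in records],
            "count_Q": [r.count_Q for r in records],
            "count_EQ": [r.count_EQ for r in records],
            "fraction_EQ": [r.fraction_EQ for r in records],
        }
    )


def correlate_composition_expression(
    comp: list[CompositionRecord] | pd.DataFrame,
    expression: pd.DataFrame,
    method: Literal["pearson", "spearman"] = "pearson",
    composition_metric: Literal["fraction_EQ", "count_EQ"] = "fraction_EQ",
    expression_column: str = "metric",
) -> CorrelationResult:
    """Correlate E+Q content with per-gene expression change.

    ``expression`` needs columns ``gene`` and ``expression_column`` (default
    ``metric``, conventionally a log2 fold change where negative means
    decreased).  Genes are inner-joined on name; losses are logged; fewer
    than 3 matched genes or a zero-variance side is an error.
    """
    comp_df = comp if isinstance(comp, pd.DataFrame) else composition_frame(comp)
    merged = comp_df.merge(expression, on="gene", how="inner")
    lost = set(comp_df["gene"]) ^ set(merged["gene"]) | set(expression["gene"]) - set(merged["gene"])
    if lost:
        logger.info("join dropped %d gene(s): %s", len(lost), sorted(lost))
    if len(merged) < 3:
        raise ValueError(f"need >= 3 genes after join, got {len(merged)}")
    x = merged[composition_metric].to_numpy(dtype=float)
    y = merged[expression_column].to_numpy(dtype=float)
    for name, v in (("composition", x), ("expression", y)):
        if np.all(v == v[0]):
            raise ValueError(f"zero variance in the {name} vector")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(
        r=float(res.statistic), p_value=float(res.pvalue), n=len(merged), method=method
    )
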
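"""Cumulative damaging-allele burden per individual and group-mean comparison.

Each individual's burden is the sum of their allele counts over the
qualifying (damaging, rare) variants in the nuclear modifier panel, plus one
allele for the homoplasmic mtDNA variant if they carry it.  Group means
(affected vs unaffected vs population controls) are compared with a pooled
Student's t-test by default; Welch and a seeded permutation test are options.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Affection, Cohort, Individual, Role

logger = logging.getLogger(__name__)

Method = Literal["student_t", "welch_t", "permutation"]


@dataclass
class BurdenComparison:
    """Two-group allele-burden comparison summary."""

    group_labels: tuple[str, str]
    group_ns: tuple[int, int]
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    method: str
    permutation_p: float | None = None

    def to_dict(self) -> dict:
        d = {
            "group_labels": list(self.group_labels),
            "group_ns": list(self.group_ns),
            "group_means": list(self.group_means),
            "group_sds": list(self.group_sds),
            "t_statistic": self.t_statistic,
            "degrees_of_freedom": self.degrees_of_freedom,
            "p_value": self.p_value,
            "method": self.method,
        }
        if self.permutation_p is not None:
            d["permutation_p"] = self.permutation_p
        return d


def individual_allele_count(individual: Individual, cohort: Cohort) -> int:
    """Cumulative damaging allele count for one cohort member.

    Sums genotype allele counts over the cohort's qualifying panel variants
    and adds 1 if the individual carries the homoplasmic mtDNA variant (a
    homoplasmic variant contributes a single allele to the burden).
    Missing genotypes count as 0.
    """
    if individual.id not in cohort.individual_ids:
        raise KeyError(f"individual {individual.id!r} not in cohort")
    total = sum(
        cohort.allele_count(individual.id, vid) for vid in sorted(cohort.qualifying_variants)
    )
    return total + (1 if individual.mt_carrier else 0)


def burden_table(cohort: Cohort) -> pd.DataFrame:
    """Per-individual burden rows with group labels.

    Columns: individual_id, family_id, group, allele_count.  Group is
    ``control`` for population controls, else the affection label; individuals
    of unknown affection are labelled ``unknown`` (and excluded by
    ``compare_groups``, with a log line).
    """
    rows = []
    for ind in cohort.individuals:
        if ind.role is Role.CONTROL:
            group = "control"
        else:
            group = ind.affection.value
        rows.append(
            {
                "individual_id": ind.id,
                "family_id": ind.family_id,
                "group": group,
                "allele_count": individual_allele_count(ind, cohort),
            }
        )
    return pd.DataFrame(rows, columns=["individual_id", "family_id", "group", "allele_count"])


def compare_group_means(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    method: Method = "student_t",
    n_perm: int = 10_000,
    seed: int | None = None,
    labels: tuple[str, str] = ("a", "b"),
) -> BurdenComparison:
    """Two-sided comparison of mean allele counts between two groups.

    ``student_t`` is the pooled-variance unpaired t-test; ``welch_t`` drops
    the equal-variance assumption; ``permutation`` shuffles group labels
    (seeded) and uses p = (1 + #{|d_perm| >= |d_obs|}) / (1 + n_perm).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    min_n = 1 if method == "permutation" else 2
    if len(a) < min_n or len(b) < min_n:
        raise ValueError(f"each group needs >= {min_n} observations for {method}")

    mean_a, mean_b = float(a.mean()), float(b.mean())
    sd_a = float(a.std(ddof=1)) if len(a) > 1 else 0.0
    sd_b = float(b.std(ddof=1)) if len(b) > 1 else 0.0

    perm_p: float | None = None
    if method == "permutation":
        if seed is None:
            raise ValueError("permutation method requires a seed")
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        d_obs = abs(mean_a - mean_b)
        n_a = len(a)
        hits = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if abs(pooled[:n_a].mean() - pooled[n_a:].mean()) >= d_obs:
                hits += 1
        perm_p = (1 + hits) / (1 + n_perm)
        t_stat, df, p = float("nan"), float("nan"), perm_p
    elif sd_a == 0 and sd_b == 0:
        # degenerate: no within-group variance at all
        df = float(len(a) + len(b) - 2)
        if mean_a == mean_b:
            t_stat, p = 0.0, 1.0
        else:
            logger.warning(
                "zero within-group variance with unequal means; "
                "p set to smallest representable positive value"
            )
            t_stat = np.inf if mean_a > mean_b else -np.inf
            p = np.nextafter(0.0, 1.0)
    else:
        equal_var = method == "student_t"
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        t_stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)

    return BurdenComparison(
        group_labels=labels,
        group_ns=(len(a), len(b)),
        group_means=(mean_a, mean_b),
        group_sds=(sd_a, sd_b),
        t_statistic=t_stat,
        degrees_of_freedom=df,
        p_value=p,
        method=method,
        permutation_p=perm_p,
    )


def compare_groups(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    method: Method = "student_t",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> BurdenComparison:
    """Compare two named groups of a ``burden_table`` output."""
    n_unknown = int((table["group"] == "unknown").sum())
    if n_unknown:
        logger.info("excluding %d individual(s) of unknown affection from comparison", n_unknown)
    counts = {
        g: table.loc[table["group"] == g, "allele_count"].to_numpy() for g in (group_a, group_b)
    }
    return compare_group_means(
        counts[group_a], counts[group_b], method=method, n_perm=n_perm, seed=seed,
        labels=(group_a, group_b),
    )


def simulate_burden_power(
    panel_freqs: Sequence[float],
    group_sizes: tuple[int, int] = (22, 12),
    effect_size: float = 1.0,
    n_sims: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    method: Method = "student_t",
) -> dict:
    """Monte-Carlo power of the burden comparison.

    Both groups draw per-individual counts as sums of Binomial(2, maf) over
    the panel variants; the first (affected) group additionally receives
    Poisson(effect_size) extra alleles, i.e. ``effect_size`` is the mean
    allele-count shift.  Returns power, Monte-Carlo SE and the settings.
    """
    if min(group_sizes) < 2:
        raise ValueError("group sizes must be >= 2")
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    rng = np.random.default_rng(seed)
    freqs = np.asarray(panel_freqs, dtype=float)
    n_a, n_b = group_sizes
    rejections = 0
    for _ in range(n_sims):
        base_a = rng.binomial(2, freqs, size=(n_a, len(freqs))).sum(axis=1)
        base_b = rng.binomial(2, freqs, size=(n_b, len(freqs))).sum(axis=1)
        if effect_size > 0:
            base_a = base_a + rng.poisson(effect_size, size=n_a)
        res = compare_group_means(base_a, base_b, method=method,
                                  seed=int(rng.integers(2**31)) if method == "permutation" else None)
        if res.p_value < alpha:
            rejections += 1
    power = rejections / n_sims
    se = float(np.sqrt(power * (1 - power) / n_sims))
    return {
        "power": power,
        "mc_se": se,
        "n_sims": n_sims,
        "alpha": alpha,
        "effect_size": effect_size,
        "group_sizes": list(group_sizes),
        "method": method,
    }
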
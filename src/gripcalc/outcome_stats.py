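"""Stratified outcome statistics: descriptive tables, nonparametric trend
tests and integer-percent contingency rates.

Registry variables are skewed, so group homogeneity across complexity strata
is tested with the tie-corrected Kruskal-Wallis test; pairwise two-sided
Mann-Whitney U follow-ups run only when the omnibus test is significant
(policy configurable). No multiple-testing correction is applied by default;
Holm adjustment of the pairwise p-values is available behind a flag.
Published contingency rates are integer percentages rounded half away from
zero, which this module reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .complexity_scoring import score_complexity
from .errors import DomainError
from .registry_model import PAIN_COLUMNS, RegistryRecord


def cohort_frame(records: Sequence[RegistryRecord]) -> pd.DataFrame:
    """Flatten registry records into an analysis DataFrame.

    Adds a recomputed ``complexity_score`` column; records with a 3-year
    recurrence are excluded (they are reported separately, not stratified).
    """
    rows = []
    for rec in records:
        if rec.outcome.recurrence_3y:
            continue
        row: dict = {}
        row.update(rec.profile.model_dump())
        row.update(rec.mesh.model_dump())
        row.update(rec.outcome.model_dump())
        row["distension"] = rec.distension
        row["complexity_score"] = score_complexity(rec.profile).score
        rows.append(row)
    return pd.DataFrame(rows)


def describe(
    cohort: pd.DataFrame, variable: str, by: str = "complexity_score"
) -> pd.DataFrame:
    """Per-stratum mean, SD, median, min, max and n for one variable.

    Strata present in ``by`` but empty for the variable appear as all-NaN
    rows (missing, not zero). Median follows the mean-of-middle-two
    convention for even n. SD is the sample SD (ddof = 1).
    """
    if variable not in cohort.columns:
        raise KeyError(f"no column {variable!r}")
    grouped = cohort.groupby(by)[variable]
    table = grouped.agg(
        mean="mean", sd="std", median="median", min="min", max="max", n="count"
    )
    table.loc[table["n"] == 0, ["mean", "sd", "median", "min", "max"]] = np.nan
    return table


@dataclass(frozen=True)
class PairwiseTest:
    strata: tuple[int, int]
    u_statistic: float
    p: float


@dataclass(frozen=True)
class TrendResult:
    variable: str
    kw_statistic: float
    kw_p: float
    pairwise: tuple[PairwiseTest, ...]


def trend_test(
    cohort: pd.DataFrame,
    variable: str,
    by: str = "complexity_score",
    alpha: float = 0.05,
    followup: Literal["gated", "always", "never"] = "gated",
    adjust: Literal[None, "holm"] = None,
) -> TrendResult:
    """Kruskal-Wallis omnibus test across strata with Mann-Whitney follow-ups.

    Both tests are tie-corrected; the U tests are two-sided, exact for small
    tie-free samples and normal-approximated otherwise (scipy's automatic
    policy). Follow-ups run when the omnibus p < ``alpha`` (``gated``),
    unconditionally (``always``) or never. Degenerate all-equal data yield
    H = 0, p = 1.
    """
    groups = {
        int(level): np.asarray(sub.dropna(), dtype=float)
        for level, sub in cohort.groupby(by)[variable]
    }
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise DomainError("need at least two strata with at least two records each")
    samples = list(groups.values())
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        kw_stat, kw_p = 0.0, 1.0
    else:
        kw_stat, kw_p = stats.kruskal(*samples)
    pairwise: list[PairwiseTest] = []
    if followup == "always" or (followup == "gated" and kw_p < alpha):
        keys = sorted(groups)
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                u, p = stats.mannwhitneyu(
                    groups[a], groups[b], alternative="two-sided"
                )
                pairwise.append(PairwiseTest(strata=(a, b), u_statistic=float(u), p=float(p)))
        if adjust == "holm" and pairwise:
            order = np.argsort([t.p for t in pairwise])
            m = len(pairwise)
            adj = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * pairwise[idx].p)
                adj[idx] = min(1.0, running)
            pairwise = [
                PairwiseTest(t.strata, t.u_statistic, float(adj[i]))
                for i, t in enumerate(pairwise)
            ]
    return TrendResult(
        variable=variable,
        kw_statistic=float(kw_stat),
        kw_p=float(kw_p),
        pairwise=tuple(pairwise),
    )


def rate_table(counts: Sequence[int], ns: Sequence[int]) -> np.ndarray:
    """Integer percentages ``round_half_away_from_zero(100 * count / n)``.

    This is the rounding under which the published contingency rows are
    reproduced from their printed counts and stratum sizes.
    """
    counts_a = np.asarray(counts, dtype=float)
    ns_a = np.asarray(ns, dtype=float)
    if counts_a.shape != ns_a.shape:
        raise DomainError("counts and ns must have the same length")
    if np.any(counts_a < 0) or np.any(ns_a <= 0):
        raise DomainError("counts must be >= 0 and ns > 0")
    if np.any(counts_a > ns_a):
        raise DomainError("count exceeds stratum size")
    return np.floor(100.0 * counts_a / ns_a + 0.5).astype(int)


def pain_trajectory(
    cohort: pd.DataFrame, by: str = "complexity_score"
) -> pd.DataFrame:
    """Median NAS per stratum (rows) per pain timepoint column.

    Mirrors the follow-up pain layout: discharge, then 1 month / 6 months /
    1 year / 3 years split rest vs. exercise.
    """
    present = [c for c in PAIN_COLUMNS if c in cohort.columns]
    return cohort.groupby(by)[present].median()
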
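"""Group-level statistics: contingency tables reconstructed from printed
percentages, chi-square tests, one-way ANOVA from raw values or from
(n, mean, SEM) summaries, and densitometry normalization.

The reconstruction path exists because phenotype-scoring experiments are
usually reported as per-group category percentages plus group sizes; the
largest-remainder rounding here recovers integer cell counts whose row sums
honor the printed group sizes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "CATEGORIES",
    "TestResult",
    "GroupSummary",
    "largest_remainder",
    "contingency_from_percentages",
    "chi_square_independence",
    "anova_oneway",
    "anova_from_summary",
    "reconstruct_group",
    "fraction_above",
    "relative_expression",
]

# Phenotype severity categories in canonical order (least to most severe).
CATEGORIES = ("normal", "mild", "moderate", "severe")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test."""

    statistic: float
    df: float | tuple[float, float]
    pvalue: float


@dataclass(frozen=True)
class GroupSummary:
    """Per-group (n, mean, SEM) triples, as printed in summary tables."""

    labels: tuple[str, ...]
    n: tuple[int, ...]
    mean: tuple[float, ...]
    sem: tuple[float, ...]

    def __post_init__(self) -> None:
        k = len(self.labels)
        if not (len(self.n) == len(self.mean) == len(self.sem) == k):
            raise InputError("labels, n, mean, sem must have equal length")
        if any(ni < 2 for ni in self.n):
            raise InputError("each group needs n >= 2 for the SEM to be defined")
        if any(s < 0 for s in self.sem):
            raise InputError("SEM must be non-negative")


def largest_remainder(n: int, fractions: Sequence[float]) -> np.ndarray:
    """Integerize n * fractions so the result sums exactly to n.

    Floors are assigned first; the remaining units go to the cells with the
    largest fractional remainders, ties broken by position (earlier first).
    """
    fr = np.asarray(fractions, dtype=float)
    raw = n * fr
    floors = np.floor(raw).astype(int)
    short = int(round(raw.sum())) - floors.sum()
    remainders = raw - floors
    # stable sort descending by remainder -> position order breaks ties
    order = np.argsort(-remainders, kind="stable")
    out = floors.copy()
    for idx in order[:short]:
        out[idx] += 1
    return out


def contingency_from_percentages(
    group_sizes: Mapping[str, int],
    percentages: Mapping[str, Mapping[str, float]],
    categories: Sequence[str] = CATEGORIES,
) -> pd.DataFrame:
    """Rebuild an integer contingency table from group sizes and percentages.

    ``percentages[group]`` maps category -> percent; categories not listed
    for a group share the remainder to 100%, assigned to the first unlisted
    category in ``categories`` order.  Counts are integerized per row by
    largest-remainder rounding, so every row sums exactly to its group size.
    """
    rows = {}
    for group, n in group_sizes.items():
        pct = dict(percentages.get(group, {}))
        unknown = set(pct) - set(categories)
        if unknown:
            raise InputError(f"unknown categories {sorted(unknown)} for {group!r}")
        total = sum(pct.values())
        if total > 100 + 1e-9:
            raise InputError(
                f"percentages for {group!r} sum to {total} > 100"
            )
        remainder = 100.0 - total
        if remainder > 1e-9:
            unlisted = [c for c in categories if c not in pct]
            if not unlisted:
                raise InputError(
                    f"percentages for {group!r} sum below 100 with no "
                    "category left for the remainder"
                )
            pct[unlisted[0]] = remainder
        fractions = [pct.get(c, 0.0) / 100.0 for c in categories]
        rows[group] = largest_remainder(n, fractions)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(categories))
    return table


def chi_square_independence(table: pd.DataFrame | np.ndarray) -> TestResult:
    """Pearson chi-square test of independence (no continuity correction)."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise InputError("table must be at least 2x2")
    if np.any(counts < 0):
        raise InputError("counts must be non-negative")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise InputError("degenerate table: a row or column margin is zero")
    res = sps.chi2_contingency(counts, correction=False)
    return TestResult(statistic=float(res.statistic), df=int(res.dof),
                      pvalue=float(res.pvalue))


def _anova_from_ss(
    ssb: float, ssw: float, df_b: int, df_w: int
) -> TestResult:
    if df_w <= 0:
        raise InputError("not enough observations for within-group df")
    msb = ssb / df_b
    msw = ssw / df_w
    if msw == 0:
        f = np.inf if msb > 0 else 0.0
    else:
        f = msb / msw
    p = float(sps.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    if f == 0.0 and msw == 0:
        p = 1.0
    return TestResult(statistic=float(f), df=(df_b, df_w), pvalue=p)


def anova_oneway(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA from raw per-group observations.

    Standard between/within sum-of-squares decomposition; F = MSB/MSW with
    p from the F(k-1, N-k) distribution.  A zero within-group variance with
    distinct means yields F = inf and p = 0.
    """
    if len(groups) < 2:
        raise InputError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise InputError("each group needs n >= 2")
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = float(np.concatenate(arrays).mean())
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((a - m) ** 2) for a, m in zip(arrays, means)))
    return _anova_from_ss(ssb, ssw, len(arrays) - 1, int(ns.sum()) - len(arrays))


def anova_from_summary(summary: GroupSummary) -> TestResult:
    """One-way ANOVA recomputed from printed (n, mean, SEM) triples.

    Since SEM = SD/sqrt(n), the within-group sum of squares of group i is
    (n_i - 1) * SD_i^2 = (n_i - 1) * n_i * SEM_i^2.
    """
    ns = np.asarray(summary.n, dtype=float)
    means = np.asarray(summary.mean, dtype=float)
    sems = np.asarray(summary.sem, dtype=float)
    grand = float(np.sum(ns * means) / ns.sum())
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(np.sum((ns - 1) * ns * sems**2))
    return _anova_from_ss(ssb, ssw, len(summary.labels) - 1,
                          int(ns.sum()) - len(summary.labels))


def reconstruct_group(n: int, mean: float, sem: float) -> np.ndarray:
    """Build n values with exactly the requested mean and SEM.

    A fixed zero-mean, unit-SD (ddof=1) pattern is scaled by SD = sem*sqrt(n)
    and shifted; useful for consistency checks between the raw-data and
    summary-statistics ANOVA routes.
    """
    if n < 2:
        raise InputError("need n >= 2")
    base = np.arange(n, dtype=float)
    base -= base.mean()
    sd = base.std(ddof=1)
    base /= sd
    return mean + base * (sem * np.sqrt(n))


def fraction_above(counts: Sequence[int], cutoff: int = 3) -> float:
    """Proportion of values strictly greater than ``cutoff``."""
    arr = np.asarray(counts)
    if arr.size == 0:
        raise InputError("empty input")
    if cutoff < 0:
        raise InputError("cutoff must be non-negative")
    return float(np.mean(arr > cutoff))


def relative_expression(
    band: Sequence[float],
    total_protein: Sequence[float],
    reference_index: int = 0,
) -> np.ndarray:
    """Densitometric relative expression, total-protein normalized.

    value_i = (band_i / total_i) / (band_ref / total_ref); the reference
    lane maps to 1.0.
    """
    band = np.asarray(band, dtype=float)
    total = np.asarray(total_protein, dtype=float)
    if band.shape != total.shape:
        raise InputError("band and total_protein must have equal length")
    if np.any(total <= 0):
        raise InputError("total protein intensities must be positive")
    norm = band / total
    ref = norm[reference_index]
    if ref == 0:
        raise InputError("reference lane has zero band intensity")
    return norm / ref
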
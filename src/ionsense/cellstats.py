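"""Per-cell ratio computation and population comparison statistics.

Per-event two-channel intensities (imaging ROIs or flow-cytometry
events) are background-corrected and converted to ratios; populations
are compared with a chi-square homogeneity test over shared bins, or a
Welch t test for small imaging samples.

The chi-square construction: shared bin edges are computed from the
pooled sample (64 equal-width bins over the central 99% range), adjacent
low-count bins are merged until every expected count is >= 5, and the
statistic is referred to a chi-square distribution with (bins - 1)
degrees of freedom. This is a declared convention of this package, not a
reproduction of any particular instrument's software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellEvent",
    "QCReport",
    "PopulationComparison",
    "per_cell_ratio",
    "compare_populations_chi2",
    "two_group_ttest",
]


@dataclass(frozen=True)
class CellEvent:
    """One cell's channel intensities plus an optional group label."""

    event_id: int
    intensities: dict[str, float]
    group: str = ""
    scatter: dict[str, float] | None = None


@dataclass
class QCReport:
    """Bookkeeping for events excluded from ratio computation."""

    n_total: int = 0
    n_excluded: int = 0
    excluded_ids: list[int] = field(default_factory=list)


@dataclass
class PopulationComparison:
    """Chi-square homogeneity comparison of two binned ratio populations."""

    group_names: tuple[str, str]
    n: tuple[int, int]
    medians: tuple[float, float]
    bin_edges: np.ndarray
    counts: tuple[np.ndarray, np.ndarray]
    statistic: float
    dof: int
    p_value: float


def per_cell_ratio(
    events: list[CellEvent],
    numerator: str,
    denominator: str,
    background: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Background-corrected per-event ratios.

    ratio = (I_num - bg_num) / (I_den - bg_den); events whose corrected
    denominator is <= 0 are excluded and counted in the QC report.
    Raises ValueError if every event is excluded.
    """
    background = background or {}
    bg_num = background.get(numerator, 0.0)
    bg_den = background.get(denominator, 0.0)
    if bg_num < 0 or bg_den < 0:
        raise ValueError("background must be >= 0")
    qc = QCReport(n_total=len(events))
    rows = []
    for ev in events:
        num = ev.intensities[numerator] - bg_num
        den = ev.intensities[denominator] - bg_den
        if den <= 0:
            qc.n_excluded += 1
            qc.excluded_ids.append(ev.event_id)
            continue
        rows.append({"event_id": ev.event_id, "ratio": num / den, "group": ev.group})
    if not rows:
        raise ValueError("all events excluded (corrected denominator <= 0)")
    return pd.DataFrame(rows), qc


def _shared_bins(pooled: np.ndarray, n_bins: int = 64) -> np.ndarray:
    """Equal-width edges over the central 99% range of the pooled sample."""
    lo, hi = np.percentile(pooled, [0.5, 99.5])
    if hi <= lo:  # degenerate (near-constant) sample
        lo, hi = lo - 0.5, hi + 0.5
    return np.linspace(lo, hi, n_bins + 1)


def _merge_low_expected(
    counts_a: np.ndarray, counts_b: np.ndarray, min_expected: float = 5.0
):
    """Merge adjacent bins until every expected count is >= min_expected."""
    a = list(counts_a.astype(float))
    b = list(counts_b.astype(float))
    n_a, n_b = sum(a), sum(b)
    total = n_a + n_b

    def expected_ok(i):
        row = a[i] + b[i]
        return (row * n_a / total >= min_expected) and (
            row * n_b / total >= min_expected
        )

    i = 0
    while i < len(a):
        if expected_ok(i) or len(a) == 1:
            i += 1
            continue
        j = i + 1 if i + 1 < len(a) else i - 1  # merge into the neighbor
        a[min(i, j)] += a[max(i, j)]
        b[min(i, j)] += b[max(i, j)]
        del a[max(i, j)], b[max(i, j)]
        i = max(i - 1, 0)
    return np.array(a), np.array(b)


def compare_populations_chi2(
    a: np.ndarray,
    b: np.ndarray,
    group_names: tuple[str, str] = ("a", "b"),
    n_bins: int = 64,
) -> PopulationComparison:
    """Chi-square homogeneity test between two ratio populations.

    Identical samples give statistic 0 and p = 1. Raises ValueError when
    fewer than 2 bins survive the expected-count merging.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 50 or len(b) < 50:
        raise ValueError("each group needs >= 50 events for a binned comparison")
    edges = _shared_bins(np.concatenate([a, b]), n_bins)
    counts_a = np.histogram(a, bins=edges)[0]
    counts_b = np.histogram(b, bins=edges)[0]
    # clip=True behavior: fold out-of-range events into the edge bins so
    # every event is counted (Sum counts = n)
    counts_a[0] += np.sum(a < edges[0])
    counts_a[-1] += np.sum(a > edges[-1])
    counts_b[0] += np.sum(b < edges[0])
    counts_b[-1] += np.sum(b > edges[-1])
    merged_a, merged_b = _merge_low_expected(counts_a, counts_b)
    if len(merged_a) < 2:
        raise ValueError(
            "fewer than 2 bins remain after expected-count merging; "
            "comparison impossible"
        )
    if np.array_equal(merged_a, merged_b):
        stat, p = 0.0, 1.0
        dof = len(merged_a) - 1
    else:
        table = np.vstack([merged_a, merged_b])
        stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return PopulationComparison(
        group_names=group_names,
        n=(len(a), len(b)),
        medians=(float(np.median(a)), float(np.median(b))),
        bin_edges=edges,
        counts=(counts_a, counts_b),
        statistic=float(stat),
        dof=int(dof),
        p_value=float(p),
    )


def two_group_ttest(a, b) -> tuple[float, float]:
    """Two-sided Welch t test on two groups of per-cell ratios.

    Zero variance in both groups with equal means is the defined p = 1
    case (no evidence of a difference).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float("inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
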
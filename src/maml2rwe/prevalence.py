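"""Biomarker frequency tabulation with exact binomial confidence intervals.

Fusion frequency is the fraction of rearranged cases over total *informative*
samples: cases with a definitive positive or negative marker call.  Cases
never tested (or QC-failed) contribute to neither numerator nor denominator.
Confidence intervals are two-sided Clopper-Pearson, which is conservative by
construction (coverage at least nominal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .cohort import CaseRecord, MarkerStatus

__all__ = [
    "FrequencyRow",
    "exact_binomial_ci",
    "fusion_frequency",
    "positive_share",
    "frequency_frame",
]

ALL_GROUP_LABEL = "all"


@dataclass(frozen=True)
class FrequencyRow:
    """One group's positivity: counts, percentage, and exact CI (percent)."""

    group_label: str
    n_positive: int
    n_total: int
    frequency_pct: float
    ci_low: float
    ci_high: float

    @property
    def fraction(self) -> float:
        return self.n_positive / self.n_total


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Two-sided Clopper-Pearson interval for a binomial proportion.

    Returns ``(low, high)`` on the proportion scale.  ``k = 0`` gives a lower
    endpoint of exactly 0 and ``k = n`` an upper endpoint of exactly 1.
    """
    if n < 1:
        raise ValueError("exact_binomial_ci requires n >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    low, high = proportion_confint(k, n, alpha=1 - level, method="beta")
    # statsmodels returns NaN at the closed boundaries; pin them.
    low = 0.0 if k == 0 else float(low)
    high = 1.0 if k == n else float(high)
    return low, high


def _marker_evaluable(cases: Sequence[CaseRecord]) -> list[CaseRecord]:
    return [c for c in cases if c.marker_status is not MarkerStatus.NOT_TESTED]


def _group_value(case: CaseRecord, group_by: str) -> str:
    if not hasattr(case, group_by):
        raise AttributeError(f"unknown grouping field {group_by!r}")
    value = getattr(case, group_by)
    return value.value if hasattr(value, "value") else str(value)


def fusion_frequency(
    cases: Sequence[CaseRecord],
    group_by: str = "primary_site",
    ci_level: float = 0.95,
) -> list[FrequencyRow]:
    """Marker positivity per group plus an overall row.

    Each group's frequency is ``100 * positives / informative`` rounded to two
    decimals (the raw fraction is recoverable from the stored counts).  Groups
    are ordered by descending denominator; the "all" row comes first.
    """
    if not cases:
        raise ValueError("fusion_frequency requires a non-empty cohort")
    evaluable = _marker_evaluable(cases)
    if not evaluable:
        raise ValueError("no marker-evaluable (informative) cases")

    counts: dict[str, list[int]] = {}
    for c in evaluable:
        key = _group_value(c, group_by)
        pos, tot = counts.setdefault(key, [0, 0])
        counts[key][0] += int(c.marker_status is MarkerStatus.POSITIVE)
        counts[key][1] += 1

    def make_row(label: str, k: int, n: int) -> FrequencyRow:
        low, high = exact_binomial_ci(k, n, ci_level)
        return FrequencyRow(
            group_label=label,
            n_positive=k,
            n_total=n,
            frequency_pct=round(100 * k / n, 2),
            ci_low=round(100 * low, 2),
            ci_high=round(100 * high, 2),
        )

    k_all = sum(v[0] for v in counts.values())
    n_all = sum(v[1] for v in counts.values())
    rows = [make_row(ALL_GROUP_LABEL, k_all, n_all)]
    for label in sorted(counts, key=lambda g: (-counts[g][1], g)):
        rows.append(make_row(label, *counts[label]))
    return rows


def positive_share(
    cases: Sequence[CaseRecord],
    group_by: str = "primary_site",
    ci_level: float = 0.95,
) -> list[FrequencyRow]:
    """Distribution of the positive cases across groups.

    Denominators are total positives (e.g. "18 of 23 positives arose in head
    and neck"); percentages are rounded to one decimal.  Returns an empty list
    with a warning if the cohort has no positives.
    """
    positives = [c for c in cases if c.marker_status is MarkerStatus.POSITIVE]
    if not positives:
        warnings.warn("positive_share: no positive cases in cohort", stacklevel=2)
        return []
    n_pos = len(positives)
    counts: dict[str, int] = {}
    for c in positives:
        key = _group_value(c, group_by)
        counts[key] = counts.get(key, 0) + 1
    rows = []
    for label in sorted(counts, key=lambda g: (-counts[g], g)):
        k = counts[label]
        low, high = exact_binomial_ci(k, n_pos, ci_level)
        rows.append(
            FrequencyRow(
                group_label=label,
                n_positive=k,
                n_total=n_pos,
                frequency_pct=round(100 * k / n_pos, 1),
                ci_low=round(100 * low, 1),
                ci_high=round(100 * high, 1),
            )
        )
    return rows


def frequency_frame(rows: Sequence[FrequencyRow]) -> pd.DataFrame:
    """Tabular view of frequency rows for export."""
    return pd.DataFrame(
        [
            {
                "group": r.group_label,
                "n_positive": r.n_positive,
                "n_total": r.n_total,
                "frequency_pct": r.frequency_pct,
                "ci_low_pct": r.ci_low,
                "ci_high_pct": r.ci_high,
            }
            for r in rows
        ]
    )
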
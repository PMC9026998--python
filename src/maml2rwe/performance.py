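"""Scenario-wise diagnostic test performance of the fusion marker.

Truth is the adjudicated final diagnosis; the index test is the marker call.
Metrics follow the standard 2x2 definitions with exact binomial confidence
intervals on each column/row denominator.  Youden's J = sens + spec - 1
summarizes a setting in one number; the combined average J expresses a
composite biomarker (imperfect rule-in screen plus near-perfect exclusion
tool) as the mean of its two J values.

Degenerate subsets are common under scenario filters, so any metric whose
denominator is zero is reported as a flagged ``None``, never coerced to 0 or
100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

from scipy import stats

from .cohort import CaseRecord, FinalDx, MarkerStatus
from .prevalence import exact_binomial_ci

__all__ = [
    "ConfusionCounts",
    "Proportion",
    "PerformanceMetrics",
    "confusion_counts",
    "performance_metrics",
    "inverted_marker_metrics",
    "combined_average_j",
    "fisher_exact_2x2",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts: marker call vs. final-diagnosis truth."""

    tp: int
    fp: int
    fn: int
    tn: int
    n_excluded: int = 0  # outside the filter or the {target, comparator} truth domain

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Proportion:
    """A percentage with its exact CI and the counts it came from."""

    pct: float
    ci_low: float
    ci_high: float
    numer: int
    denom: int


def _proportion(k: int, n: int, ci_level: float) -> Optional[Proportion]:
    if n == 0:
        return None
    low, high = exact_binomial_ci(k, n, ci_level)
    return Proportion(
        pct=round(100 * k / n, 1),
        ci_low=round(100 * low, 1),
        ci_high=round(100 * high, 1),
        numer=k,
        denom=n,
    )


@dataclass(frozen=True)
class PerformanceMetrics:
    """Sens/spec/PPV/NPV with exact CIs plus Youden's J.

    ``youden_j`` is the unrounded fraction (``None`` when sensitivity or
    specificity is undefined); ``youden_j_2dp`` is the 2-decimal report value.
    """

    counts: ConfusionCounts
    sensitivity: Optional[Proportion]
    specificity: Optional[Proportion]
    ppv: Optional[Proportion]
    npv: Optional[Proportion]
    youden_j: Optional[float]

    @property
    def youden_j_2dp(self) -> Optional[float]:
        return None if self.youden_j is None else round(self.youden_j, 2)


def confusion_counts(
    cases: Sequence[CaseRecord],
    positive_dx: FinalDx = FinalDx.MEC,
    setting_filter: Optional[Callable[[CaseRecord], bool]] = None,
    filter_name: str = "setting_filter",
    comparator_dx: Optional[FinalDx] = None,
) -> ConfusionCounts:
    """Cross-tabulate marker calls against final diagnoses.

    Truth is restricted to the ``positive_dx`` vs. ``comparator_dx``
    differential (default MEC vs. ASC); cases outside that domain, untested
    cases, and cases failing ``setting_filter`` are excluded and counted in
    ``n_excluded``.
    """
    if comparator_dx is None:
        comparator_dx = FinalDx.ASC if positive_dx is not FinalDx.ASC else FinalDx.MEC
    tp = fp = fn = tn = excluded = 0
    for case in cases:
        in_domain = (
            case.final_dx in (positive_dx, comparator_dx)
            and case.marker_status in (MarkerStatus.POSITIVE, MarkerStatus.NEGATIVE)
        )
        if not in_domain or (setting_filter is not None and not setting_filter(case)):
            excluded += 1
            continue
        truth = case.final_dx is positive_dx
        test = case.marker_status is MarkerStatus.POSITIVE
        if truth and test:
            tp += 1
        elif truth:
            fn += 1
        elif test:
            fp += 1
        else:
            tn += 1
    if tp + fp + fn + tn == 0:
        raise ValueError(f"no cases remain after applying {filter_name!r}")
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, n_excluded=excluded)


def performance_metrics(counts: ConfusionCounts, ci_level: float = 0.95) -> PerformanceMetrics:
    """Standard 2x2 metrics from counts; zero denominators yield flagged None."""
    sens = _proportion(counts.tp, counts.tp + counts.fn, ci_level)
    spec = _proportion(counts.tn, counts.tn + counts.fp, ci_level)
    ppv = _proportion(counts.tp, counts.tp + counts.fp, ci_level)
    npv = _proportion(counts.tn, counts.tn + counts.fn, ci_level)
    j = None
    if sens is not None and spec is not None:
        j = sens.numer / sens.denom + spec.numer / spec.denom - 1.0
    return PerformanceMetrics(
        counts=counts, sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, youden_j=j
    )


def inverted_marker_metrics(
    counts: ConfusionCounts, ci_level: float = 0.95
) -> PerformanceMetrics:
    """Performance of marker *absence* as an indicator of the complementary
    diagnosis (e.g. absence of the rearrangement as a rule-in for ASC).

    Equivalent to swapping truth labels and negating the test, i.e. evaluating
    the table (tp', fp', fn', tn') = (tn, fn, fp, tp).  Applying the inversion
    twice returns the original metrics.
    """
    swapped = ConfusionCounts(
        tp=counts.tn, fp=counts.fn, fn=counts.fp, tn=counts.tp, n_excluded=counts.n_excluded
    )
    return performance_metrics(swapped, ci_level)


def combined_average_j(j_screen: float, j_exclusion: float) -> int:
    """Composite value of a two-role biomarker: mean of the screening-role and
    exclusion-role J indices, as an integer percentage."""
    for name, j in (("j_screen", j_screen), ("j_exclusion", j_exclusion)):
        if not 0.0 <= j <= 1.0:
            raise ValueError(f"{name}={j} outside [0, 1]")
    return round(100 * (j_screen + j_exclusion) / 2)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Uses the minimum-likelihood rule: p is the sum of hypergeometric
    probabilities of all tables (with the observed margins) no more probable
    than the observed one.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("Fisher's exact test requires positive margins")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
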
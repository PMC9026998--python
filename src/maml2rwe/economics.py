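"""Cost impact of selective versus universal molecular testing.

Compares the cost of genotyping every eligible differential-diagnosis case
against the tests actually performed, and splits actual spending into
value-added and non-contributory shares.  All currency arithmetic is in
integer cents so printed totals are exact products of the fee-schedule unit
cost.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CostReport", "cost_impact", "DEFAULT_UNIT_COST"]

DEFAULT_UNIT_COST = 597.91  # clinical laboratory fee schedule, CPT 81445


@dataclass(frozen=True)
class CostReport:
    n_eligible: int
    n_tested: int
    n_value_added: int
    unit_cost: float
    cost_universal: float
    cost_actual: float
    savings: float
    pct_reduction: float  # 1 decimal
    cost_value_added: float
    cost_non_contributory: float


def _cents(amount: float) -> int:
    return round(amount * 100)


def cost_impact(
    n_eligible: int,
    n_tested: int,
    n_value_added: int,
    unit_cost: float = DEFAULT_UNIT_COST,
) -> CostReport:
    """Selective-testing cost report.

    ``n_eligible`` is the universe of cases that would be genotyped under a
    test-everything policy, ``n_tested`` the tests actually performed, and
    ``n_value_added`` the tested cases where the result carried diagnostic
    value (typically the extended benefit count).  Satisfies exactly, in cent
    arithmetic: ``savings = cost_universal - cost_actual`` and
    ``cost_value_added + cost_non_contributory = cost_actual``.
    """
    if not 0 <= n_value_added <= n_tested <= n_eligible:
        raise ValueError(
            "counts must satisfy 0 <= n_value_added <= n_tested <= n_eligible"
        )
    if unit_cost <= 0:
        raise ValueError("unit_cost must be positive")

    unit_cents = _cents(unit_cost)
    universal = n_eligible * unit_cents
    actual = n_tested * unit_cents
    value_added = n_value_added * unit_cents
    non_contrib = actual - value_added
    savings = universal - actual
    pct_reduction = round(100 * savings / universal, 1) if universal else 0.0

    return CostReport(
        n_eligible=n_eligible,
        n_tested=n_tested,
        n_value_added=n_value_added,
        unit_cost=unit_cents / 100,
        cost_universal=universal / 100,
        cost_actual=actual / 100,
        savings=savings / 100,
        pct_reduction=pct_reduction,
        cost_value_added=value_added / 100,
        cost_non_contributory=non_contrib / 100,
    )
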
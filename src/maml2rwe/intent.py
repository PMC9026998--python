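"""Test-order-intent classification from report timelines.

The ordering pathologist never records *why* a molecular test was ordered, but
the relationship between the surgical-pathology and molecular report timelines
reveals it.  A case whose molecular result was signed out no later than the
surgical report was *held* for the result (diagnostic intent); otherwise the
surgical report was finalized without it (confirmatory intent).  Confirmatory
orders placed more than a threshold number of days (default 30) after surgical
sign-out are presumed to serve therapeutic target identification rather than
diagnosis and form the confirmatory-therapeutic subset.

Cases where the final diagnosis differs from the working diagnosis are flagged
"molecularly changed"; an UNKNOWN working diagnosis is always counted as
changed because the molecular result resolved it.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from .cohort import CaseRecord, FinalDx, MarkerStatus, WorkingDx

__all__ = [
    "Intent",
    "IntentLabel",
    "IntentSummary",
    "BenefitReport",
    "ClassificationError",
    "classify_intent",
    "is_changed",
    "intent_summary",
    "benefit_accounting",
]

DEFAULT_THERAPEUTIC_THRESHOLD_DAYS = 30


class Intent(str, Enum):
    DIAGNOSTIC = "diagnostic"
    CONFIRMATORY = "confirmatory"
    CONFIRMATORY_THERAPEUTIC = "confirmatory_therapeutic"

    @property
    def is_confirmatory(self) -> bool:
        return self is not Intent.DIAGNOSTIC


class ClassificationError(ValueError):
    """A case cannot be classified; the message names the offending field."""


@dataclass(frozen=True)
class IntentLabel:
    """Derived classification of one test order."""

    intent: Intent
    changed: bool
    delay_days: int  # t_mol_order - t_surg_signout (negative = ordered earlier)


def is_changed(case: CaseRecord) -> bool:
    """True when molecular results shifted (or resolved) the diagnosis.

    The comparison collapses the final marker substates to the three
    diagnostic groups {MEC, ASC, OTHER}.  An UNKNOWN working diagnosis counts
    as changed: the molecular result resolved an open differential.
    """
    if case.working_dx is WorkingDx.UNKNOWN:
        return True
    return case.working_dx.value != case.final_dx.value


def classify_intent(
    case: CaseRecord,
    threshold_days: int = DEFAULT_THERAPEUTIC_THRESHOLD_DAYS,
) -> IntentLabel:
    """Classify one case's molecular order from its report timeline.

    Diagnostic intent requires the molecular result at (or before) surgical
    sign-out, i.e. ``t_mol_signout <= t_surg_signout``; the tie is diagnostic
    because the result was available when the report was finalized.  All other
    cases are confirmatory, upgraded to confirmatory-therapeutic when the
    order postdates surgical sign-out by more than ``threshold_days``.
    """
    for field_name in ("t_surg_order", "t_surg_signout", "t_mol_order", "t_mol_signout"):
        if getattr(case, field_name) is None:
            raise ClassificationError(f"missing timeline field {field_name!r}")

    delay = case.t_mol_order - case.t_surg_signout
    if case.t_mol_signout <= case.t_surg_signout:
        intent = Intent.DIAGNOSTIC
    elif delay > threshold_days:
        intent = Intent.CONFIRMATORY_THERAPEUTIC
    else:
        intent = Intent.CONFIRMATORY
    return IntentLabel(intent=intent, changed=is_changed(case), delay_days=delay)


@dataclass
class IntentSummary:
    """Intent-by-working-diagnosis contingency with headline ratios."""

    counts: pd.DataFrame  # index: intent values, columns: working_dx values
    n_total: int
    n_confirmatory: int  # including the therapeutic subset
    n_diagnostic: int
    n_therapeutic: int
    ratio_confirmatory_to_diagnostic: Optional[float]  # 1 decimal; None if no diagnostic
    ratio_ex_therapeutic: Optional[float]


def intent_summary(
    cases: Sequence[CaseRecord],
    threshold_days: int = DEFAULT_THERAPEUTIC_THRESHOLD_DAYS,
) -> IntentSummary:
    """Tabulate intents against working diagnoses and report both headline
    confirmatory:diagnostic ratios (with and without the therapeutic subset)."""
    if not cases:
        raise ValueError("intent_summary requires at least one case")
    labels = [classify_intent(c, threshold_days) for c in cases]

    table = pd.DataFrame(
        0,
        index=[i.value for i in Intent],
        columns=[w.value for w in WorkingDx],
        dtype=int,
    )
    for case, lab in zip(cases, labels):
        table.loc[lab.intent.value, case.working_dx.value] += 1

    n_diag = sum(1 for l in labels if l.intent is Intent.DIAGNOSTIC)
    n_ther = sum(1 for l in labels if l.intent is Intent.CONFIRMATORY_THERAPEUTIC)
    n_conf = len(labels) - n_diag

    def ratio(num: int) -> Optional[float]:
        return None if n_diag == 0 else round(num / n_diag, 1)

    return IntentSummary(
        counts=table,
        n_total=len(labels),
        n_confirmatory=n_conf,
        n_diagnostic=n_diag,
        n_therapeutic=n_ther,
        ratio_confirmatory_to_diagnostic=ratio(n_conf) if n_diag else None,
        ratio_ex_therapeutic=ratio(n_conf - n_ther) if n_diag else None,
    )


@dataclass
class BenefitReport:
    """Accounting of cases where the molecular result added diagnostic value.

    Core benefit counts changed diagnoses plus positively confirmed
    marker-positive MEC; the extended benefit additionally credits unchanged
    marker-negative ASC confirmations (exclusion value of a negative result).
    Percentages are integer-rounded shares of all tested cases.
    """

    n_total: int
    n_changed: int
    n_confirmed_positive_mec: int
    n_confirmed_negative_asc: int
    n_core: int
    n_extended: int
    pct_core: int
    pct_extended: int


def benefit_accounting(cases: Iterable[CaseRecord]) -> BenefitReport:
    cases = list(cases)
    if not cases:
        raise ValueError("benefit_accounting requires at least one case")
    n_changed = sum(1 for c in cases if is_changed(c))
    n_pos_mec = sum(
        1
        for c in cases
        if not is_changed(c)
        and c.working_dx is WorkingDx.MEC
        and c.marker_status is MarkerStatus.POSITIVE
    )
    n_neg_asc = sum(
        1
        for c in cases
        if not is_changed(c)
        and c.final_dx is FinalDx.ASC
        and c.marker_status is MarkerStatus.NEGATIVE
    )
    n_core = n_changed + n_pos_mec
    n_ext = n_core + n_neg_asc
    n = len(cases)
    return BenefitReport(
        n_total=n,
        n_changed=n_changed,
        n_confirmed_positive_mec=n_pos_mec,
        n_confirmed_negative_asc=n_neg_asc,
        n_core=n_core,
        n_extended=n_ext,
        pct_core=round(100 * n_core / n),
        pct_extended=round(100 * n_ext / n),
    )
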
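"""Empirical Markov model of diagnostic state transitions.

The working diagnosis (before molecular testing) and the final diagnosis
(after result integration) are treated as states of a memoryless process with
a single transition.  Origins are the 3 working states {MEC, ASC, OTHER}
(UNKNOWN merges into OTHER); destinations are the 4 final states that split
MEC on the marker result: {MEC_pos, MEC_neg, ASC, OTHER}.

Estimation is pure conditioning and normalization of the observed counts - no
smoothing and no pseudocounts.  With cohorts this small the estimates are
summary statistics of one practice, not converged probabilities, so cells
with zero counts are surfaced through an ``unobserved_mask`` (and a separate
structural-zero mask for the transition the marker rule forbids: an ASC
working diagnosis can never land in marker-positive MEC) rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import CaseRecord, FinalDx, MarkerStatus, WorkingDx

__all__ = [
    "OriginState",
    "DestinationState",
    "TransitionMatrix",
    "StateAssignmentError",
    "origin_state",
    "destination_state",
    "estimate_transitions",
    "to_flows",
    "simulate_chain",
]


class OriginState(str, Enum):
    MEC = "MEC"
    ASC = "ASC"
    OTHER = "OTHER"


class DestinationState(str, Enum):
    MEC_POS = "MEC_pos"
    MEC_NEG = "MEC_neg"
    ASC = "ASC"
    OTHER = "OTHER"


ORIGINS: tuple[OriginState, ...] = tuple(OriginState)
DESTINATIONS: tuple[DestinationState, ...] = tuple(DestinationState)


class StateAssignmentError(ValueError):
    """A case's final state cannot be derived (e.g. MEC final, marker untested)."""


def origin_state(case: CaseRecord) -> OriginState:
    """Working diagnosis collapsed to the 3-state origin space."""
    if case.working_dx in (WorkingDx.OTHER, WorkingDx.UNKNOWN):
        return OriginState.OTHER
    return OriginState(case.working_dx.value)


def destination_state(case: CaseRecord) -> DestinationState:
    """Final state; MEC splits on the marker, ASC/OTHER ignore it."""
    if case.final_dx is FinalDx.MEC:
        if case.marker_status is MarkerStatus.POSITIVE:
            return DestinationState.MEC_POS
        if case.marker_status is MarkerStatus.NEGATIVE:
            return DestinationState.MEC_NEG
        raise StateAssignmentError(
            f"case {case.case_id!r}: final MEC requires a definitive marker result"
        )
    return DestinationState(case.final_dx.value)


@dataclass
class TransitionMatrix:
    """Counts and row-normalized transition probabilities (3 origins x 4
    destinations).

    ``probs`` rows with no observations are all-NaN and flagged through
    ``row_observed``; ``unobserved_mask`` marks zero-count cells and
    ``structural_zero`` the single cell excluded by the marker rule
    (ASC -> MEC_pos).
    """

    counts: np.ndarray  # (3, 4) int
    probs: np.ndarray  # (3, 4) float, NaN rows where unobserved
    row_totals: np.ndarray  # (3,) int
    row_observed: np.ndarray  # (3,) bool
    unobserved_mask: np.ndarray  # (3, 4) bool, True where counts == 0
    structural_zero: np.ndarray = field(
        default_factory=lambda: _structural_zero_mask()
    )

    def prob(self, origin: OriginState, dest: DestinationState) -> float:
        return float(self.probs[ORIGINS.index(origin), DESTINATIONS.index(dest)])

    def count(self, origin: OriginState, dest: DestinationState) -> int:
        return int(self.counts[ORIGINS.index(origin), DESTINATIONS.index(dest)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probs,
            index=[o.value for o in ORIGINS],
            columns=[d.value for d in DESTINATIONS],
        )


def _structural_zero_mask() -> np.ndarray:
    mask = np.zeros((len(ORIGINS), len(DESTINATIONS)), dtype=bool)
    mask[ORIGINS.index(OriginState.ASC), DESTINATIONS.index(DestinationState.MEC_POS)] = True
    return mask


def estimate_transitions(cases: Iterable[CaseRecord]) -> TransitionMatrix:
    """Maximum-likelihood (count/normalize) transition estimates.

    Rows with zero observations are flagged, not imputed; rows with
    observations sum to 1 exactly up to floating rounding.
    """
    counts = np.zeros((len(ORIGINS), len(DESTINATIONS)), dtype=int)
    for case in cases:
        i = ORIGINS.index(origin_state(case))
        j = DESTINATIONS.index(destination_state(case))
        counts[i, j] += 1
    row_totals = counts.sum(axis=1)
    row_observed = row_totals > 0
    probs = np.full(counts.shape, np.nan)
    for i, total in enumerate(row_totals):
        if total > 0:
            probs[i] = counts[i] / total
    return TransitionMatrix(
        counts=counts,
        probs=probs,
        row_totals=row_totals,
        row_observed=row_observed,
        unobserved_mask=counts == 0,
    )


def to_flows(cases: Iterable[CaseRecord]) -> pd.DataFrame:
    """Origin -> destination flow table for alluvial/sankey plotting.

    One row per observed (origin, destination) pair with its count; counts sum
    to the cohort size.  Columns: origin, destination, count.
    """
    matrix = estimate_transitions(cases)
    rows = []
    for i, origin in enumerate(ORIGINS):
        for j, dest in enumerate(DESTINATIONS):
            if matrix.counts[i, j] > 0:
                rows.append(
                    {
                        "origin": origin.value,
                        "destination": dest.value,
                        "count": int(matrix.counts[i, j]),
                    }
                )
    return pd.DataFrame(rows, columns=["origin", "destination", "count"])


def simulate_chain(
    matrix: TransitionMatrix,
    origin_counts: Sequence[int],
    seed: int,
) -> np.ndarray:
    """Draw final-state counts by multinomial sampling per origin row.

    ``origin_counts`` gives the number of cases starting in each origin state
    (ordered as ``ORIGINS``); returns a (3, 4) array of destination counts.
    Sampling from a row with no estimated probabilities is an error.
    """
    origin_counts = np.asarray(origin_counts, dtype=int)
    if origin_counts.shape != (len(ORIGINS),):
        raise ValueError(f"origin_counts must have length {len(ORIGINS)}")
    if (origin_counts < 0).any():
        raise ValueError("origin_counts must be nonnegative")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(matrix.counts)
    for i, n in enumerate(origin_counts):
        if n == 0:
            continue
        if not matrix.row_observed[i]:
            raise ValueError(
                f"cannot sample origin {ORIGINS[i].value!r}: row has no estimates"
            )
        out[i] = rng.multinomial(n, matrix.probs[i])
    return out
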
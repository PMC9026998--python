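"""Delphi survey analytics: relative importance index, subjective rank order,
and intra-rater reliability.

Each scenario is a triplet (working diagnosis, marker result, final
diagnosis).  Respondents score every scenario on a 0-100 value slider and,
separately, produce an explicit rank order of all scenarios (1 = most
important).  Two aggregate orderings result:

* RII (relative importance index): sum of ratings / (scale max x number of
  raters), in [0, 1], higher = more important.
* SRO (subjective rank order): sum of explicit ranks over respondents with a
  complete permutation, lower = more important.

The two orderings are reported side by side and may disagree.  Intra-rater
reliability is the Spearman correlation between a respondent's explicit ranks
and the ranks implied by their own ratings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import FinalDx, MarkerStatus, WorkingDx

__all__ = [
    "Scenario",
    "SurveyResponse",
    "DEFAULT_SCENARIOS",
    "rii",
    "sro",
    "rank_consistency",
    "aggregate_table",
    "read_survey",
    "write_survey",
]


@dataclass(frozen=True)
class Scenario:
    """A clinical scenario: working dx, marker result, final dx."""

    working_dx: WorkingDx
    marker_result: MarkerStatus
    final_dx: FinalDx
    label: str = ""

    @property
    def key(self) -> str:
        sign = "pos" if self.marker_result is MarkerStatus.POSITIVE else "neg"
        return f"{self.working_dx.value.lower()}_{sign}_{self.final_dx.value.lower()}"


def _scn(w: str, m: str, f: str, label: str) -> Scenario:
    return Scenario(WorkingDx(w), MarkerStatus(m), FinalDx(f), label)


#: The seven scenarios spanned by the MEC/ASC differential: confirmations,
#: re-classifications, and molecularly unchanged outcomes.
DEFAULT_SCENARIOS: tuple[Scenario, ...] = (
    _scn("MEC", "positive", "MEC", "Molecular confirmation of suspected MEC"),
    _scn("ASC", "negative", "ASC", "Confirmation of ASC via marker exclusion"),
    _scn("ASC", "positive", "MEC", "Re-classified ASC to MEC via marker"),
    _scn("OTHER", "positive", "MEC", "Re-classified other to MEC via marker"),
    _scn("MEC", "negative", "MEC", "MEC molecularly unchanged (negative)"),
    _scn("OTHER", "negative", "OTHER", "Other confirmed via marker exclusion"),
    _scn("OTHER", "positive", "OTHER", "Other molecularly unchanged (positive)"),
)


@dataclass
class SurveyResponse:
    """One respondent: ratings per scenario key, optional complete rank order."""

    respondent_id: str
    ratings: dict[str, float]
    ranks: Optional[dict[str, int]] = None
    years_experience: float = 0.0
    subspecialty: str = "other"

    def has_complete_ranks(self, scenario_keys: Sequence[str]) -> bool:
        if self.ranks is None:
            return False
        if set(self.ranks) != set(scenario_keys):
            return False
        return sorted(self.ranks.values()) == list(range(1, len(scenario_keys) + 1))


def rii(
    responses: Sequence[SurveyResponse],
    scenario: Scenario | str,
    likert_max: int = 100,
    per_item_n: bool = True,
) -> Optional[float]:
    """Relative importance index: sum(V) / (A x N).

    V are the ratings for the scenario, A the scale maximum, N the number of
    raters.  With ``per_item_n`` (default) N counts respondents who rated this
    scenario, so partial response does not deflate the score; with
    ``per_item_n=False`` N is the full panel size.  Returns None when nobody
    rated the scenario.
    """
    key = scenario.key if isinstance(scenario, Scenario) else scenario
    values = [r.ratings[key] for r in responses if key in r.ratings]
    if not values:
        return None
    n = len(values) if per_item_n else len(responses)
    return float(sum(values)) / (likert_max * n)


@dataclass(frozen=True)
class SroResult:
    total: int
    n_rankers: int


def sro(
    responses: Sequence[SurveyResponse],
    scenario: Scenario | str,
    scenario_keys: Optional[Sequence[str]] = None,
) -> Optional[SroResult]:
    """Subjective rank order: sum of explicit ranks over complete rankers.

    Only respondents carrying a complete permutation of ``scenario_keys``
    contribute (a partial ranking would bias the sum downward).  Lower totals
    mean higher importance; for R complete rankers of S scenarios the total
    over all scenarios is exactly R*S*(S+1)/2.
    """
    key = scenario.key if isinstance(scenario, Scenario) else scenario
    if scenario_keys is None:
        scenario_keys = [s.key for s in DEFAULT_SCENARIOS]
    rankers = [r for r in responses if r.has_complete_ranks(scenario_keys)]
    if not rankers:
        return None
    return SroResult(
        total=sum(r.ranks[key] for r in rankers),  # type: ignore[index]
        n_rankers=len(rankers),
    )


def rank_consistency(response: SurveyResponse) -> Optional[float]:
    """Intra-rater reliability: Spearman correlation between the explicit rank
    permutation and the ranks implied by the respondent's own ratings
    (descending; rating ties receive average implied ranks)."""
    if response.ranks is None:
        return None
    keys = sorted(response.ranks)
    if not all(k in response.ratings for k in keys):
        return None
    explicit = np.array([response.ranks[k] for k in keys], dtype=float)
    implied = stats.rankdata([-response.ratings[k] for k in keys], method="average")
    rho = stats.spearmanr(explicit, implied).statistic
    return float(rho)


def aggregate_table(
    responses: Sequence[SurveyResponse],
    scenarios: Sequence[Scenario] = DEFAULT_SCENARIOS,
    likert_max: int = 100,
) -> pd.DataFrame:
    """Ranked scenario table with both orderings side by side.

    Columns: scenario key, label, rii (2 decimals, raw in ``rii_raw``),
    rii_rank, sro, sro_rank, n_raters, n_rankers.  RII ties are broken by the
    lower (better) SRO, then by scenario key; the table is sorted by RII rank.
    """
    if not responses:
        raise ValueError("aggregate_table requires at least one response")
    keys = [s.key for s in scenarios]
    rows = []
    for s in scenarios:
        r_raw = rii(responses, s, likert_max)
        sro_res = sro(responses, s, keys)
        n_raters = sum(1 for r in responses if s.key in r.ratings)
        rows.append(
            {
                "scenario": s.key,
                "label": s.label,
                "rii_raw": r_raw,
                "rii": None if r_raw is None else round(r_raw, 2),
                "sro": None if sro_res is None else sro_res.total,
                "n_raters": n_raters,
                "n_rankers": 0 if sro_res is None else sro_res.n_rankers,
            }
        )
    df = pd.DataFrame(rows)

    # RII rank: higher RII = rank 1; ties broken by lower SRO then key.
    sro_for_tiebreak = df["sro"].fillna(np.inf)
    order = sorted(
        df.index,
        key=lambda i: (
            -(df.loc[i, "rii_raw"] if df.loc[i, "rii_raw"] is not None else -np.inf),
            sro_for_tiebreak[i],
            df.loc[i, "scenario"],
        ),
    )
    df["rii_rank"] = 0
    for rank, i in enumerate(order, start=1):
        df.loc[i, "rii_rank"] = rank

    sro_order = sorted(
        df.index, key=lambda i: (sro_for_tiebreak[i], df.loc[i, "scenario"])
    )
    df["sro_rank"] = 0
    for rank, i in enumerate(sro_order, start=1):
        df.loc[i, "sro_rank"] = rank

    df = df.sort_values("rii_rank").reset_index(drop=True)
    return df[
        ["scenario", "label", "rii", "rii_raw", "rii_rank", "sro", "sro_rank",
         "n_raters", "n_rankers"]
    ]


# ---------------------------------------------------------------------------
# CSV schema: respondent_id, years_experience, subspecialty,
#             rating_<key>..., rank_<key>...


def read_survey(path, scenarios: Sequence[Scenario] = DEFAULT_SCENARIOS) -> list[SurveyResponse]:
    keys = [s.key for s in scenarios]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for base in ("respondent_id",):
        if base not in df.columns:
            raise ValueError(f"missing mandatory column {base!r}")
    out = []
    for _, row in df.iterrows():
        ratings = {
            k: float(row[f"rating_{k}"])
            for k in keys
            if f"rating_{k}" in df.columns and str(row[f"rating_{k}"]).strip()
        }
        ranks = {
            k: int(row[f"rank_{k}"])
            for k in keys
            if f"rank_{k}" in df.columns and str(row[f"rank_{k}"]).strip()
        }
        out.append(
            SurveyResponse(
                respondent_id=str(row["respondent_id"]),
                ratings=ratings,
                ranks=ranks or None,
                years_experience=float(row.get("years_experience", 0) or 0),
                subspecialty=str(row.get("subspecialty", "other") or "other"),
            )
        )
    return out


def write_survey(
    responses: Iterable[SurveyResponse],
    path,
    scenarios: Sequence[Scenario] = DEFAULT_SCENARIOS,
) -> None:
    keys = [s.key for s in scenarios]
    rows = []
    for r in responses:
        row: dict = {
            "respondent_id": r.respondent_id,
            "years_experience": r.years_experience,
            "subspecialty": r.subspecialty,
        }
        for k in keys:
            row[f"rating_{k}"] = r.ratings.get(k, "")
            row[f"rank_{k}"] = r.ranks.get(k, "") if r.ranks else ""
        rows.append(row)
    cols = ["respondent_id", "years_experience", "subspecialty"]
    cols += [f"rating_{k}" for k in keys] + [f"rank_{k}" for k in keys]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
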
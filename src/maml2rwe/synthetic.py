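"""Synthetic cohorts and survey responses.

Two kinds of synthetic data are provided:

* stochastic generators (:func:`generate_cohort`, :func:`generate_survey`)
  that draw cohorts with the statistical structure the analysis assumes -
  working-diagnosis mix, working-to-final transition probabilities, intent
  mix, and report-timeline gaps - for property and recovery testing;

* deterministic reference cohorts (:func:`reference_cohort`,
  :func:`screening_cohort`) that reproduce, case by case, the marginal
  structure of a tertiary-care fusion-testing practice: a 55-case test-order
  series over the MEC/ASC differential, and an 8106-sample pan-tumor
  screening series with 23 rearranged cases concentrated in head and neck.

All draws derive from a single integer seed; identical seeds give identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort import (
    CaseRecord,
    FinalDx,
    FusionCall,
    Grade,
    MarkerStatus,
    PrimarySite,
    WorkingDx,
)
from .intent import Intent
from .markov import DESTINATIONS, ORIGINS, DestinationState, OriginState
from .survey import DEFAULT_SCENARIOS, Scenario, SurveyResponse

__all__ = [
    "CohortSpec",
    "TimingParams",
    "SurveySpec",
    "SpecError",
    "generate_cohort",
    "generate_survey",
    "reference_cohort",
    "screening_cohort",
]

_CRTC1_MAML2 = FusionCall(gene_5p="CRTC1", exon_5p=1, gene_3p="MAML2", exon_3p=2)


class SpecError(ValueError):
    """The generation spec is internally inconsistent."""


@dataclass
class TimingParams:
    """Mean day-gaps for timeline construction (shifted-geometric draws).

    ``surg_tat_mean``: surgical order to sign-out; ``mol_tat_mean``: molecular
    order to sign-out; ``confirm_gap_mean``: sign-out to molecular order for
    plain confirmatory cases; ``therapeutic_gap_mean``: extra delay beyond the
    therapeutic threshold.
    """

    surg_tat_mean: float = 10.0
    mol_tat_mean: float = 14.0
    confirm_gap_mean: float = 7.0
    therapeutic_gap_mean: float = 30.0
    therapeutic_threshold_days: int = 30


@dataclass
class CohortSpec:
    """Parameters of a synthetic test-order cohort.

    Defaults mirror the observed 55-case series: working mix 25 ASC / 23 MEC /
    7 other, transition rows matching the empirical matrix, and an intent mix
    of 11 diagnostic / 26 confirmatory / 18 confirmatory-therapeutic.
    """

    n_cases: int = 55
    # origin order: MEC, ASC, OTHER (matches markov.ORIGINS)
    working_dx_weights: Sequence[float] = (23 / 55, 25 / 55, 7 / 55)
    # rows: origin; columns: MEC_pos, MEC_neg, ASC, OTHER (markov.DESTINATIONS)
    transition_probs: Sequence[Sequence[float]] = (
        (7 / 23, 6 / 23, 9 / 23, 1 / 23),
        (0.0, 0.0, 24 / 25, 1 / 25),
        (2 / 7, 0.0, 1 / 7, 4 / 7),
    )
    # intent order: diagnostic, confirmatory, confirmatory_therapeutic
    intent_mix: Sequence[float] = (11 / 55, 26 / 55, 18 / 55)
    timing: TimingParams = field(default_factory=TimingParams)
    # site order matches PrimarySite enum order
    site_weights: Sequence[float] = (0.75, 0.0, 0.0, 0.0, 0.2, 0.05)
    # P(low, intermediate, high) given marker status
    grade_given_positive: Sequence[float] = (0.7, 0.2, 0.1)
    grade_given_negative: Sequence[float] = (0.3, 0.3, 0.4)
    forbid_asc_to_mec_pos: bool = True

    def validate(self) -> None:
        def check_simplex(name: str, v: Sequence[float]) -> None:
            arr = np.asarray(v, dtype=float)
            if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
                raise SpecError(f"{name} must be a probability vector summing to 1")

        check_simplex("working_dx_weights", self.working_dx_weights)
        check_simplex("intent_mix", self.intent_mix)
        check_simplex("site_weights", self.site_weights)
        check_simplex("grade_given_positive", self.grade_given_positive)
        check_simplex("grade_given_negative", self.grade_given_negative)
        probs = np.asarray(self.transition_probs, dtype=float)
        if probs.shape != (len(ORIGINS), len(DESTINATIONS)):
            raise SpecError("transition_probs must be 3x4")
        for i, origin in enumerate(ORIGINS):
            check_simplex(f"transition_probs[{origin.value}]", probs[i])
        if self.forbid_asc_to_mec_pos and probs[1, 0] > 0:
            raise SpecError(
                "ASC -> MEC_pos transition mass conflicts with the marker rule"
            )
        if self.n_cases < 0:
            raise SpecError("n_cases must be nonnegative")


def _shifted_geometric(rng: np.random.Generator, mean: float) -> int:
    """Integer gap >= 1 with approximately the requested mean."""
    if mean <= 1:
        return 1
    return int(rng.geometric(1.0 / mean))


def _timeline(
    rng: np.random.Generator, intent: Intent, timing: TimingParams
) -> tuple[int, int, int]:
    """(t_surg_signout, t_mol_order, t_mol_signout) realizing the intent."""
    surg_tat = _shifted_geometric(rng, timing.surg_tat_mean)
    mol_tat = _shifted_geometric(rng, timing.mol_tat_mean)
    if intent is Intent.DIAGNOSTIC:
        # Case held: molecular result available at (or before) sign-out.
        mol_order = int(rng.integers(0, max(surg_tat, 1)))
        mol_signout = mol_order + mol_tat
        surg_signout = mol_signout + int(rng.integers(0, 4))
    elif intent is Intent.CONFIRMATORY:
        surg_signout = surg_tat
        # Ordered around sign-out, never beyond the therapeutic threshold.
        gap = min(
            _shifted_geometric(rng, timing.confirm_gap_mean) - 4,
            timing.therapeutic_threshold_days,
        )
        mol_order = max(0, surg_signout + gap)
        mol_signout = mol_order + mol_tat
        if mol_signout <= surg_signout:  # must postdate sign-out
            mol_signout = surg_signout + 1
    else:  # therapeutic: ordered well after sign-out
        surg_signout = surg_tat
        gap = timing.therapeutic_threshold_days + _shifted_geometric(
            rng, timing.therapeutic_gap_mean
        )
        mol_order = surg_signout + gap
        mol_signout = mol_order + mol_tat
    return surg_signout, mol_order, mol_signout


_DEST_TO_FINAL = {
    DestinationState.MEC_POS: (FinalDx.MEC, MarkerStatus.POSITIVE),
    DestinationState.MEC_NEG: (FinalDx.MEC, MarkerStatus.NEGATIVE),
    DestinationState.ASC: (FinalDx.ASC, MarkerStatus.NEGATIVE),
    DestinationState.OTHER: (FinalDx.OTHER, MarkerStatus.NEGATIVE),
}


def generate_cohort(spec: CohortSpec, seed: int) -> list[CaseRecord]:
    """Draw a cohort of ``spec.n_cases`` records.

    Working diagnoses, final states, intents and timelines are sampled
    independently per case from the spec's distributions; marker status and
    fusion calls are derived from the final state (marker-positive MEC carries
    the canonical CRTC1-MAML2 call).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    probs = np.asarray(spec.transition_probs, dtype=float)
    intents = (Intent.DIAGNOSTIC, Intent.CONFIRMATORY, Intent.CONFIRMATORY_THERAPEUTIC)
    sites = tuple(PrimarySite)

    cases = []
    for i in range(spec.n_cases):
        origin = ORIGINS[rng.choice(len(ORIGINS), p=np.asarray(spec.working_dx_weights))]
        dest = DESTINATIONS[rng.choice(len(DESTINATIONS), p=probs[ORIGINS.index(origin)])]
        final_dx, marker = _DEST_TO_FINAL[dest]
        intent = intents[rng.choice(3, p=np.asarray(spec.intent_mix))]
        surg_signout, mol_order, mol_signout = _timeline(rng, intent, spec.timing)
        grade_probs = (
            spec.grade_given_positive
            if marker is MarkerStatus.POSITIVE
            else spec.grade_given_negative
        )
        grade = tuple(Grade)[rng.choice(3, p=np.asarray(grade_probs))]
        site = sites[rng.choice(len(sites), p=np.asarray(spec.site_weights))]
        cases.append(
            CaseRecord(
                case_id=f"SYN{i:04d}",
                primary_site=site,
                subsite="",
                working_dx=WorkingDx(origin.value),
                final_dx=final_dx,
                marker_status=marker,
                fusion=_CRTC1_MAML2 if marker is MarkerStatus.POSITIVE else None,
                grade=grade,
                t_surg_order=0,
                t_surg_signout=surg_signout,
                t_mol_order=mol_order,
                t_mol_signout=mol_signout,
            ).validate()
        )
    return cases


# ---------------------------------------------------------------------------
# Deterministic reference cohorts


def _mk_case(
    idx: int,
    working: WorkingDx,
    dest: DestinationState,
    pattern: str,
    site: PrimarySite,
    subsite: str,
    grade: Optional[Grade] = None,
    positive_other_final: bool = False,
) -> CaseRecord:
    """Build one reference case with a canonical timeline for its pattern.

    Patterns (surgical sign-out fixed at day 10):
      ``held``        - molecular result back before sign-out (diagnostic);
      ``pre_order``   - ordered before sign-out, result after (confirmatory);
      ``post_order``  - ordered 10 days after sign-out (confirmatory);
      ``late``        - ordered 40 days after sign-out (therapeutic).
    """
    timelines = {
        "held": (2, 9, 10),  # mol_order, mol_signout, surg_signout
        "pre_order": (8, 20, 10),
        "post_order": (20, 32, 10),
        "late": (50, 60, 10),
    }
    mol_order, mol_signout, surg_signout = timelines[pattern]
    if positive_other_final:
        final_dx, marker = FinalDx.OTHER, MarkerStatus.POSITIVE
    else:
        final_dx, marker = _DEST_TO_FINAL[dest]
    return CaseRecord(
        case_id=f"T{idx:03d}",
        primary_site=site,
        subsite=subsite,
        working_dx=working,
        final_dx=final_dx,
        marker_status=marker,
        fusion=_CRTC1_MAML2 if marker is MarkerStatus.POSITIVE else None,
        grade=grade,
        t_surg_order=0,
        t_surg_signout=surg_signout,
        t_mol_order=mol_order,
        t_mol_signout=mol_signout,
    ).validate()


def reference_cohort() -> list[CaseRecord]:
    """Deterministic 55-case test-order series over the MEC/ASC differential.

    Marginals, all of which the analysis modules reproduce:

    * 25 working ASC (20 confirmatory of which 15 therapeutic-delay, 5
      diagnostic; finals: 24 ASC, 1 other);
    * 23 working MEC (19 confirmatory with 8 marker-positive, 4 diagnostic;
      finals: 7 marker-positive MEC, 6 marker-negative MEC, 9 ASC, 1 other);
    * 7 working other/unknown (5 confirmatory other, 2 diagnostic unknown;
      finals: 2 marker-positive MEC, 1 ASC, 4 other).

    Hence 44 confirmatory vs. 11 diagnostic orders, 18 orders placed more
    than 30 days after surgical sign-out (15 of them ASC), 14 changed
    diagnoses, 7 positively confirmed MEC, and overall marker sensitivity
    9/15 against the final MEC-vs-ASC truth.

    Note the marker-consistency rule caps working-MEC positives at 8 (7 final
    MEC plus 1 final other): a ninth positive could not land in any final
    state compatible with its result.
    """
    D = DestinationState
    cases: list[CaseRecord] = []
    idx = 0

    def add(working, dest, pattern, site, subsite, grade=None, pos_other=False):
        nonlocal idx
        idx += 1
        cases.append(
            _mk_case(idx, working, dest, pattern, site, subsite, grade, pos_other)
        )

    hn, lung, other = PrimarySite.HEAD_AND_NECK, PrimarySite.LUNG, PrimarySite.OTHER

    # --- working MEC: 19 confirmatory -------------------------------------
    # 7 pre_order (ordered before sign-out, signed out before result), all
    # marker-positive confirmations; grades reflect the low-grade enrichment
    # of fusion-positive tumors.
    for _ in range(7):
        add(WorkingDx.MEC, D.MEC_POS, "pre_order", hn, "parotid", Grade.LOW)
    # 10 post_order: 4 negative MEC, 5 revised to ASC, 1 positive with final
    # other; 6 high-grade among the confirmatory negatives.
    for _ in range(4):
        add(WorkingDx.MEC, D.MEC_NEG, "post_order", hn, "parotid", Grade.HIGH)
    for i in range(5):
        add(WorkingDx.MEC, D.ASC, "post_order", hn, "parotid",
            Grade.HIGH if i < 2 else Grade.INTERMEDIATE)
    add(WorkingDx.MEC, D.OTHER, "post_order", hn, "parotid", Grade.LOW, pos_other=True)
    # 2 late (therapeutic) orders, both revised to ASC.
    for _ in range(2):
        add(WorkingDx.MEC, D.ASC, "late", hn, "parotid", Grade.INTERMEDIATE)
    # --- working MEC: 4 diagnostic (held), all marker-negative -------------
    for _ in range(2):
        add(WorkingDx.MEC, D.MEC_NEG, "held", hn, "parotid", Grade.LOW)
    for _ in range(2):
        add(WorkingDx.MEC, D.ASC, "held", hn, "parotid", Grade.INTERMEDIATE)

    # --- working ASC: 20 confirmatory (15 late), 5 diagnostic --------------
    add(WorkingDx.ASC, D.OTHER, "pre_order", lung, "lung")  # the one revision
    add(WorkingDx.ASC, D.ASC, "pre_order", lung, "lung")
    for _ in range(3):
        add(WorkingDx.ASC, D.ASC, "post_order", lung, "lung")
    for _ in range(15):
        add(WorkingDx.ASC, D.ASC, "late", lung, "lung")
    for _ in range(5):
        add(WorkingDx.ASC, D.ASC, "held", lung, "lung")

    # --- working OTHER: 5 confirmatory ------------------------------------
    add(WorkingDx.OTHER, D.MEC_POS, "pre_order", hn, "oropharynx", Grade.LOW)
    for _ in range(3):
        add(WorkingDx.OTHER, D.OTHER, "post_order", other, "soft tissue")
    add(WorkingDx.OTHER, D.OTHER, "late", other, "soft tissue")
    # --- working UNKNOWN: 2 diagnostic (resolved by the molecular result) --
    add(WorkingDx.UNKNOWN, D.MEC_POS, "held", hn, "oropharynx", Grade.LOW)
    add(WorkingDx.UNKNOWN, D.ASC, "held", lung, "lung")

    assert len(cases) == 55
    return cases


#: Site margins of the pan-tumor screening series: (total, positives).
_SCREENING_MARGINS: dict[PrimarySite, tuple[int, int]] = {
    PrimarySite.HEAD_AND_NECK: (307, 18),
    PrimarySite.BRAIN: (742, 1),
    PrimarySite.BREAST: (414, 2),
    PrimarySite.THYMUS: (16, 1),
    PrimarySite.LUNG: (2364, 1),
    PrimarySite.OTHER: (4263, 0),
}

#: Fusion partners of the positives by site (5' partner, 5' exon, 3' exon, n).
_SCREENING_FUSIONS: dict[PrimarySite, list[tuple[FusionCall, int]]] = {
    PrimarySite.HEAD_AND_NECK: [
        (FusionCall("CRTC1", 1, "MAML2", 2), 17),
        (FusionCall("CRTC3", 1, "MAML2", 2), 1),
    ],
    PrimarySite.BRAIN: [(FusionCall("YAP1", 5, "MAML2", 2), 1)],
    PrimarySite.BREAST: [(FusionCall("CRTC1", 1, "MAML2", 2), 2)],
    PrimarySite.THYMUS: [(FusionCall("KMT2A", 10, "MAML2", 2), 1)],
    PrimarySite.LUNG: [(FusionCall("SAMSN1", 2, "MAML2", 3), 1)],
}


def screening_cohort() -> list[CaseRecord]:
    """Deterministic 8106-sample pan-tumor screening series.

    23 marker-positive cases distributed over sites (18 in head and neck,
    where the site total is 307), with per-site fusion-partner calls.  Only
    the fields feeding frequency tabulation are meaningful; timelines are
    trivial placeholders and working diagnoses are recorded as unknown
    (screening, not a targeted differential).
    """
    cases: list[CaseRecord] = []
    idx = 0
    for site, (total, n_pos) in _SCREENING_MARGINS.items():
        fusions: list[FusionCall] = []
        for call, n in _SCREENING_FUSIONS.get(site, []):
            fusions.extend([call] * n)
        assert len(fusions) == n_pos
        for i in range(total):
            idx += 1
            positive = i < n_pos
            cases.append(
                CaseRecord(
                    case_id=f"S{idx:05d}",
                    primary_site=site,
                    subsite="",
                    working_dx=WorkingDx.UNKNOWN,
                    final_dx=FinalDx.MEC if positive else FinalDx.OTHER,
                    marker_status=(
                        MarkerStatus.POSITIVE if positive else MarkerStatus.NEGATIVE
                    ),
                    fusion=fusions[i] if positive else None,
                    t_surg_order=0,
                    t_surg_signout=1,
                    t_mol_order=1,
                    t_mol_signout=2,
                )
            )
    assert len(cases) == 8106
    return cases


# ---------------------------------------------------------------------------
# Survey generation


@dataclass
class SurveySpec:
    """Parameters of a synthetic expert-survey panel.

    ``latent_importance`` holds each scenario's true importance on [0, 1];
    defaults follow the observed consensus profile over the seven scenarios.
    Ratings are the latent value on the Likert scale plus Gaussian noise,
    clipped to the scale; explicit ranks order a second noisy realization, and
    only ``rank_completion_rate`` of respondents return a complete
    permutation (the observed panel had 13 of 15).
    """

    n_respondents: int = 15
    n_scenarios: int = 7
    latent_importance: Sequence[float] = (0.80, 0.65, 0.68, 0.59, 0.39, 0.51, 0.43)
    rating_noise_sd: float = 10.0
    rank_completion_rate: float = 13 / 15
    likert_max: int = 100
    scenarios: Sequence[Scenario] = DEFAULT_SCENARIOS

    def validate(self) -> None:
        if self.n_scenarios < 2:
            raise SpecError("n_scenarios must be >= 2")
        if not 0 <= self.rank_completion_rate <= 1:
            raise SpecError("rank_completion_rate must be in [0, 1]")
        if len(self.latent_importance) != self.n_scenarios:
            raise SpecError("latent_importance length must equal n_scenarios")
        if len(self.scenarios) < self.n_scenarios:
            raise SpecError("not enough scenarios for n_scenarios")
        if self.rating_noise_sd < 0:
            raise SpecError("rating_noise_sd must be nonnegative")


def generate_survey(spec: SurveySpec, seed: int) -> list[SurveyResponse]:
    """Draw one panel of survey responses.

    Exactly ``round(rank_completion_rate * n_respondents)`` respondents carry
    complete rank permutations.  With zero rating noise every respondent's
    explicit ranks equal the latent-importance order.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    keys = [s.key for s in spec.scenarios[: spec.n_scenarios]]
    latent = np.asarray(spec.latent_importance, dtype=float) * spec.likert_max

    n_complete = round(spec.rank_completion_rate * spec.n_respondents)
    complete_ids = set(
        rng.choice(spec.n_respondents, size=n_complete, replace=False).tolist()
    )
    subspecialties = ["head_and_neck"] * 7 + ["molecular"] * 5 + ["other"] * 3

    responses = []
    for r in range(spec.n_respondents):
        noise = rng.normal(0.0, spec.rating_noise_sd, size=spec.n_scenarios)
        ratings_arr = np.clip(np.round(latent + noise), 0, spec.likert_max)
        ratings = {k: float(v) for k, v in zip(keys, ratings_arr)}
        ranks = None
        if r in complete_ids:
            rank_noise = rng.normal(0.0, spec.rating_noise_sd, size=spec.n_scenarios)
            score = latent + rank_noise
            # rank 1 = most important (highest score); deterministic ties.
            order = np.argsort(-score, kind="stable")
            ranks = {keys[j]: int(pos + 1) for pos, j in enumerate(order)}
        responses.append(
            SurveyResponse(
                respondent_id=f"R{r + 1:02d}",
                ratings=ratings,
                ranks=ranks,
                years_experience=float(4 + rng.integers(0, 37)),
                subspecialty=subspecialties[r % len(subspecialties)],
            )
        )
    return responses
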
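"""Synthetic generators: determinism, spec checks, parameter recovery, and
the marginal structure of the deterministic reference cohorts."""

import dataclasses

import numpy as np
import pytest

from maml2rwe.cohort import FinalDx, MarkerStatus, WorkingDx
from maml2rwe.intent import Intent, classify_intent, is_changed
from maml2rwe.markov import (
    DestinationState,
    OriginState,
    destination_state,
    estimate_transitions,
    origin_state,
)
from maml2rwe.survey import DEFAULT_SCENARIOS
from maml2rwe.synthetic import (
    CohortSpec,
    SpecError,
    SurveySpec,
    generate_cohort,
    generate_survey,
    reference_cohort,
    screening_cohort,
)


class TestGenerateCohort:
    def test_zero_cases(self):
        assert generate_cohort(CohortSpec(n_cases=0), seed=1) == []

    def test_same_seed_same_cohort(self):
        spec = CohortSpec(n_cases=40)
        assert generate_cohort(spec, seed=11) == generate_cohort(spec, seed=11)
        assert generate_cohort(spec, seed=11) != generate_cohort(spec, seed=12)

    def test_all_cases_satisfy_record_invariants(self):
        for case in generate_cohort(CohortSpec(n_cases=200), seed=3):
            assert case.validation_errors() == []

    def test_infeasible_asc_to_mec_pos_mass_rejected(self):
        spec = CohortSpec(
            transition_probs=(
                (7 / 23, 6 / 23, 9 / 23, 1 / 23),
                (0.5, 0.0, 0.46, 0.04),
                (2 / 7, 0.0, 1 / 7, 4 / 7),
            )
        )
        with pytest.raises(SpecError, match="marker rule"):
            generate_cohort(spec, seed=0)

    def test_non_simplex_weights_rejected(self):
        with pytest.raises(SpecError):
            generate_cohort(CohortSpec(working_dx_weights=(0.5, 0.4, 0.3)), seed=0)

    def test_asc_to_asc_rate_recovered_within_3_se(self):
        """ASC-origin cases keep the ASC diagnosis at the spec'd 0.96 rate.

        Binomial sampling-error oracle: at n ASC-origin draws the empirical
        frequency lies within 3*sqrt(p(1-p)/n) of p = 0.96.
        """
        p = 0.96
        spec = CohortSpec(
            n_cases=5000,
            transition_probs=(
                (7 / 23, 6 / 23, 9 / 23, 1 / 23),
                (0.0, 0.0, p, 1 - p),
                (2 / 7, 0.0, 1 / 7, 4 / 7),
            ),
        )
        cases = generate_cohort(spec, seed=2024)
        asc = [c for c in cases if c.working_dx is WorkingDx.ASC]
        kept = sum(c.final_dx is FinalDx.ASC for c in asc)
        se = np.sqrt(p * (1 - p) / len(asc))
        assert abs(kept / len(asc) - p) < 3 * se

    def test_full_matrix_recovery_within_3_se(self):
        """estimate_transitions on a generated cohort recovers every spec cell."""
        spec = CohortSpec(n_cases=5000)
        cases = generate_cohort(spec, seed=7)
        est = estimate_transitions(cases)
        target = np.asarray(spec.transition_probs)
        for i in range(3):
            n = est.row_totals[i]
            for j in range(4):
                p = target[i, j]
                se = np.sqrt(p * (1 - p) / n)
                assert abs(est.probs[i, j] - p) <= 3 * se + 1e-12

    def test_intents_realized_by_timelines(self):
        """Drawn intents are recoverable from the constructed timelines."""
        spec = CohortSpec(n_cases=1000)
        cases = generate_cohort(spec, seed=5)
        labels = [classify_intent(c).intent for c in cases]
        fractions = {i: labels.count(i) / len(labels) for i in Intent}
        # intent mix (0.2, ~0.47, ~0.33); allow 3 SE binomial slack
        for intent, target in zip(Intent, (11 / 55, 26 / 55, 18 / 55)):
            se = np.sqrt(target * (1 - target) / len(labels))
            assert abs(fractions[intent] - target) < 3 * se


class TestReferenceCohort:
    def test_size_and_working_mix(self, cohort55):
        assert len(cohort55) == 55
        mix = {w: sum(c.working_dx is w for c in cohort55) for w in WorkingDx}
        assert mix[WorkingDx.ASC] == 25
        assert mix[WorkingDx.MEC] == 23
        assert mix[WorkingDx.OTHER] + mix[WorkingDx.UNKNOWN] == 7
        assert mix[WorkingDx.UNKNOWN] == 2

    def test_every_record_valid(self, cohort55):
        for case in cohort55:
            assert case.validation_errors() == []

    def test_intent_marginals(self, cohort55):
        labels = [classify_intent(c) for c in cohort55]
        n_diag = sum(l.intent is Intent.DIAGNOSTIC for l in labels)
        n_conf = len(labels) - n_diag
        assert (n_conf, n_diag) == (44, 11)

    def test_18_late_orders_mostly_asc(self, cohort55):
        late = [c for c in cohort55 if classify_intent(c).delay_days > 30]
        assert len(late) == 18
        assert sum(c.working_dx is WorkingDx.ASC for c in late) == 15

    def test_final_state_counts_by_origin(self, cohort55):
        est = estimate_transitions(cohort55)
        assert est.counts.tolist() == [
            [7, 6, 9, 1],
            [0, 0, 24, 1],
            [2, 0, 1, 4],
        ]

    def test_mec_row_probs_round_to_printed_values(self, cohort55):
        """(7,6,9,1)/23 rounds to (0.3, 0.26, 0.4, 0.04) and sums to 1."""
        est = estimate_transitions(cohort55)
        mec = est.probs[0]
        assert [round(p, 1) for p in mec[[0, 2]]] == [0.3, 0.4]
        assert [round(p, 2) for p in mec[[1, 3]]] == [0.26, 0.04]
        assert mec.sum() == pytest.approx(1.0)

    def test_changed_diagnoses_total_14(self, cohort55):
        assert sum(is_changed(c) for c in cohort55) == 14


class TestScreeningCohort:
    def test_margins(self, screening):
        assert len(screening) == 8106
        positives = [c for c in screening if c.marker_status is MarkerStatus.POSITIVE]
        assert len(positives) == 23
        hn = [c for c in screening if c.primary_site.value == "head_and_neck"]
        assert len(hn) == 307
        assert sum(c.marker_status is MarkerStatus.POSITIVE for c in hn) == 18

    def test_fusion_partner_tally(self, screening):
        partners = {}
        for c in screening:
            if c.fusion is not None:
                partners[c.fusion.gene_5p] = partners.get(c.fusion.gene_5p, 0) + 1
        assert partners == {"CRTC1": 19, "CRTC3": 1, "YAP1": 1, "KMT2A": 1, "SAMSN1": 1}


class TestGenerateSurvey:
    def test_determinism(self):
        spec = SurveySpec()
        a = generate_survey(spec, seed=9)
        b = generate_survey(spec, seed=9)
        assert [r.ratings for r in a] == [r.ratings for r in b]
        assert [r.ranks for r in a] == [r.ranks for r in b]

    def test_noiseless_ranks_follow_latent_order(self):
        spec = SurveySpec(rating_noise_sd=0.0, rank_completion_rate=1.0)
        keys = [s.key for s in DEFAULT_SCENARIOS]
        latent_order = sorted(
            range(7), key=lambda i: -spec.latent_importance[i]
        )
        expected = {keys[j]: pos + 1 for pos, j in enumerate(latent_order)}
        for resp in generate_survey(spec, seed=4):
            assert resp.ranks == expected

    def test_exact_completion_count(self):
        spec = SurveySpec(n_respondents=15, rank_completion_rate=13 / 15)
        responses = generate_survey(spec, seed=1)
        keys = [s.key for s in DEFAULT_SCENARIOS]
        complete = [r for r in responses if r.has_complete_ranks(keys)]
        assert len(complete) == 13

    def test_ratings_clipped_to_scale(self):
        spec = SurveySpec(rating_noise_sd=80.0)
        for resp in generate_survey(spec, seed=2):
            assert all(0 <= v <= 100 for v in resp.ratings.values())

    def test_invalid_spec_rejected(self):
        with pytest.raises(SpecError):
            generate_survey(SurveySpec(n_scenarios=1), seed=0)
        with pytest.raises(SpecError):
            generate_survey(SurveySpec(rank_completion_rate=1.2), seed=0)
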
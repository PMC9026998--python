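"""Diagnostic performance metrics, the composite J index, and Fisher's exact
test (checked against full hypergeometric enumeration)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import make_case
from maml2rwe.cohort import FinalDx, MarkerStatus, WorkingDx
from maml2rwe.intent import Intent, classify_intent
from maml2rwe.performance import (
    ConfusionCounts,
    combined_average_j,
    confusion_counts,
    fisher_exact_2x2,
    inverted_marker_metrics,
    performance_metrics,
)


def fisher_enum_oracle(a, b, c, d):
    """Two-sided Fisher p by brute-force enumeration of all tables with the
    observed margins, summing hypergeometric probabilities <= observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = table_prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = table_prob(x)
        if p <= p_obs * (1 + 1e-7):  # tolerate float ties, as scipy does
            total += p
    return min(total, 1.0)


class TestConfusionCounts:
    def test_direct_construction(self):
        # 3 marker-positive MEC, 2 negative MEC, 0 positive ASC, 5 negative ASC
        cases = (
            [make_case(10, 2, 8, "MEC", "MEC", "positive") for _ in range(3)]
            + [make_case(10, 2, 8, "MEC", "MEC", "negative") for _ in range(2)]
            + [make_case(10, 2, 8, "ASC", "ASC", "negative") for _ in range(5)]
        )
        cc = confusion_counts(cases)
        assert (cc.tp, cc.fn, cc.fp, cc.tn) == (3, 2, 0, 5)

    def test_reference_confirmatory_mec_positive_rate(self, cohort55):
        """8 of the 19 confirmatory working-MEC orders are marker-positive."""
        conf_mec = [
            c
            for c in cohort55
            if c.working_dx is WorkingDx.MEC
            and classify_intent(c).intent is not Intent.DIAGNOSTIC
        ]
        assert len(conf_mec) == 19
        n_pos = sum(c.marker_status is MarkerStatus.POSITIVE for c in conf_mec)
        assert n_pos == 8

    def test_reference_overall_sensitivity_60(self, cohort55):
        cc = confusion_counts(cohort55)
        pm = performance_metrics(cc)
        assert pm.sensitivity.pct == 60.0
        assert pm.specificity.pct == 100.0

    def test_excluding_filter_raises(self, cohort55):
        with pytest.raises(ValueError, match="nothing"):
            confusion_counts(
                cohort55, setting_filter=lambda c: False, filter_name="nothing"
            )

    def test_matches_brute_force_recount_on_random_cohorts(self):
        """confusion_counts agrees with a direct per-case recount."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            cases = []
            for _ in range(rng.integers(1, 30)):
                final = rng.choice(["MEC", "ASC", "OTHER"])
                marker = rng.choice(["positive", "negative", "not_tested"])
                if final == "ASC" and marker == "positive":
                    marker = "negative"
                cases.append(make_case(10, 2, 8, "MEC", final, marker))
            try:
                cc = confusion_counts(cases)
            except ValueError:
                assert not any(
                    c.final_dx in (FinalDx.MEC, FinalDx.ASC)
                    and c.marker_status is not MarkerStatus.NOT_TESTED
                    for c in cases
                )
                continue
            tp = sum(
                c.final_dx is FinalDx.MEC and c.marker_status is MarkerStatus.POSITIVE
                for c in cases
            )
            fn = sum(
                c.final_dx is FinalDx.MEC and c.marker_status is MarkerStatus.NEGATIVE
                for c in cases
            )
            tn = sum(
                c.final_dx is FinalDx.ASC and c.marker_status is MarkerStatus.NEGATIVE
                for c in cases
            )
            assert (cc.tp, cc.fn, cc.fp, cc.tn) == (tp, fn, 0, tn)


class TestPerformanceMetrics:
    def test_sens_spec_to_j(self):
        # sens 62% spec 100% -> J 0.62 (e.g. 31/50 and 20/20)
        pm = performance_metrics(ConfusionCounts(tp=31, fn=19, fp=0, tn=20))
        assert pm.sensitivity.pct == 62.0
        assert pm.specificity.pct == 100.0
        assert pm.youden_j_2dp == 0.62

    def test_small_table_arithmetic(self):
        pm = performance_metrics(ConfusionCounts(tp=3, fn=2, fp=0, tn=5))
        assert pm.sensitivity.pct == 60.0
        assert pm.youden_j_2dp == 0.60
        assert pm.ppv.pct == 100.0
        assert pm.npv.pct == pytest.approx(71.4)

    def test_degenerate_rows_flagged_not_zeroed(self):
        pm = performance_metrics(ConfusionCounts(tp=0, fn=0, fp=1, tn=4))
        assert pm.sensitivity is None
        assert pm.youden_j is None
        assert pm.specificity is not None

    def test_all_zero_table_is_undefined_not_exception(self):
        pm = performance_metrics(ConfusionCounts(tp=0, fn=0, fp=0, tn=0))
        assert pm.sensitivity is None and pm.ppv is None and pm.youden_j is None

    def test_j_identity_invariant(self):
        """J always equals sens + spec - 1 (fractions) when both defined."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            tp, fp, fn, tn = rng.integers(0, 30, size=4)
            pm = performance_metrics(ConfusionCounts(int(tp), int(fp), int(fn), int(tn)))
            if pm.youden_j is not None:
                sens = pm.sensitivity.numer / pm.sensitivity.denom
                spec = pm.specificity.numer / pm.specificity.denom
                assert pm.youden_j == pytest.approx(sens + spec - 1, abs=1e-9)

    def test_j_depends_only_on_sens_and_spec(self):
        """Scaling the column prevalences changes PPV/NPV but not J."""
        a = performance_metrics(ConfusionCounts(tp=6, fn=4, fp=0, tn=10))
        b = performance_metrics(ConfusionCounts(tp=30, fn=20, fp=0, tn=10))
        assert a.youden_j == pytest.approx(b.youden_j)
        assert a.npv.pct != b.npv.pct


class TestInvertedMarker:
    def test_printed_exclusion_metrics(self):
        """Absence of the marker as a rule-in for ASC: 100% sensitive,
        62.2% specific on the (23, 14, 0, 20) table."""
        inv = inverted_marker_metrics(ConfusionCounts(tp=23, fn=14, fp=0, tn=20))
        assert inv.sensitivity.pct == 100.0
        assert inv.specificity.pct == 62.2

    def test_fp_zero_forces_inverted_sensitivity_100(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tp, fn, tn = (int(v) for v in rng.integers(1, 20, size=3))
            inv = inverted_marker_metrics(ConfusionCounts(tp=tp, fn=fn, fp=0, tn=tn))
            assert inv.sensitivity.pct == 100.0

    def test_double_inversion_is_identity(self):
        cc = ConfusionCounts(tp=9, fn=6, fp=2, tn=30)
        once = inverted_marker_metrics(cc)
        twice = inverted_marker_metrics(once.counts)
        assert twice.counts == cc
        assert twice.sensitivity == performance_metrics(cc).sensitivity


class TestCombinedAverageJ:
    @pytest.mark.parametrize(
        "j1, j2, expected", [(0.70, 1.00, 85), (1.0, 1.0, 100), (0.0, 0.0, 0)]
    )
    def test_examples(self, j1, j2, expected):
        assert combined_average_j(j1, j2) == expected

    @pytest.mark.parametrize("j1, j2", [(-0.1, 0.5), (0.5, 1.2)])
    def test_domain_errors(self, j1, j2):
        with pytest.raises(ValueError):
            combined_average_j(j1, j2)


class TestFisherExact:
    def test_grade_table(self):
        """High-grade enrichment among tested MEC: 6/19 vs 7/70."""
        assert fisher_exact_2x2(6, 13, 7, 63) == pytest.approx(0.029, abs=0.001)

    def test_no_association_p_is_1(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 3, 4)

    @settings(max_examples=150, derandomize=True)
    @given(
        a=st.integers(0, 12),
        b=st.integers(0, 12),
        c=st.integers(0, 12),
        d=st.integers(0, 12),
    )
    def test_agrees_with_enumeration_oracle(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        p = fisher_exact_2x2(a, b, c, d)
        assert 0 < p <= 1
        assert p == pytest.approx(fisher_enum_oracle(a, b, c, d), rel=1e-6)

    def test_testing_rate_table(self):
        """Marker testing rates 25/85 vs 23/108 are not significantly
        different; the exact two-sided p agrees with enumeration."""
        p = fisher_exact_2x2(25, 60, 23, 85)
        assert p == pytest.approx(fisher_enum_oracle(25, 60, 23, 85), rel=1e-9)
        assert p > 0.05
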
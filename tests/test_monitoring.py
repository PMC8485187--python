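"""Fortnightly monitoring: schedule, GP alerts, completer outcome classes."""

import itertools

import pytest

from helpers import GAD_BAND_TOTAL, PHQ_BAND_TOTAL, make_record, make_timeline
from stepscreen import (
    SCHEDULE_WEEKS,
    SeverityBand,
    build_schedule,
    classify_remitter,
    classify_responder,
    classify_worsened,
    detect_alerts,
    last_assessment,
    triage,
)
from stepscreen.errors import NonCompleterError, ScheduleError

B = SeverityBand


class TestSchedule:
    def test_nine_fortnights_over_18_weeks(self):
        schedule = build_schedule(triage(make_record(7, 2)))
        assert schedule == (2, 4, 6, 8, 10, 12, 14, 16, 18)
        assert len(schedule) * 2 == 18

    def test_screen_negative_not_monitored(self):
        with pytest.raises(ScheduleError):
            build_schedule(triage(make_record(2, 2)))

    def test_negative_baseline_timeline_rejected(self):
        with pytest.raises(ScheduleError):
            make_timeline(2, 2, [])

    def test_unscheduled_week_rejected(self):
        t = make_timeline(7, 2, [(2, 7, 2)])
        with pytest.raises(ScheduleError):
            detect_alerts(t, 3)

    def test_optout_truncates_schedule(self):
        t = make_timeline(7, 2, [(2, 7, 2)], opted_out_week=4)
        assert t.scheduled_weeks() == (2, 4)
        with pytest.raises(ScheduleError):
            detect_alerts(t, 6)


class TestAlerts:
    def test_improvement_one_band_down(self):
        t = make_timeline(12, 2, [(2, 12, 2), (4, 7, 2)])
        a = detect_alerts(t, 4)
        assert a.improvement and not a.deterioration

    def test_deterioration_one_band_up_on_gad(self):
        t = make_timeline(7, 7, [(2, 7, 7), (4, 7, 12)])
        a = detect_alerts(t, 4)
        assert a.deterioration and not a.improvement

    def test_no_band_change_no_alert(self):
        t = make_timeline(7, 2, [(2, 7, 2), (4, 8, 3)])
        a = detect_alerts(t, 4)
        assert not a.improvement and not a.deterioration

    def test_week2_compares_against_baseline(self):
        t = make_timeline(12, 2, [(2, 7, 2)])
        assert detect_alerts(t, 2).improvement

    def test_missed_previous_uses_last_completed_reference(self):
        # Week 4 missed; week 6 compares against week 2, not the gap.
        t = make_timeline(12, 2, [(2, 12, 2), (4, None, None), (6, 7, 2)])
        assert detect_alerts(t, 6).improvement

    def test_cross_instrument_co_occurrence(self):
        # PHQ-9 down a band while GAD-7 up a band: both alerts raise.
        t = make_timeline(12, 7, [(2, 7, 12)])
        a = detect_alerts(t, 2)
        assert a.improvement and a.deterioration

    def test_nonadherent_two_consecutive_misses(self):
        t = make_timeline(7, 2, [(2, None, None), (4, None, None)])
        assert detect_alerts(t, 4).nonadherent
        assert not detect_alerts(t, 2).nonadherent

    def test_nonadherence_re_raised_on_new_pair(self):
        t = make_timeline(
            7, 2, [(2, None, None), (4, None, None), (6, 7, 2), (8, None, None), (10, None, None)]
        )
        assert detect_alerts(t, 4).nonadherent
        assert not detect_alerts(t, 6).nonadherent
        assert not detect_alerts(t, 8).nonadherent
        assert detect_alerts(t, 10).nonadherent

    def test_severe_unchanging_at_week4(self):
        t = make_timeline(22, 2, [(2, 22, 2), (4, 21, 2)])
        a = detect_alerts(t, 4)
        assert a.severe_unchanging
        assert not detect_alerts(t, 2).severe_unchanging

    def test_severe_improved_not_flagged(self):
        t = make_timeline(22, 2, [(2, 12, 2), (4, 12, 2)])
        assert not detect_alerts(t, 4).severe_unchanging

    def test_severe_unchanging_per_instrument(self):
        # GAD-7 severe at baseline must itself improve; PHQ-9 improving
        # does not clear the anxiety flag.
        t = make_timeline(22, 16, [(2, 12, 16), (4, 12, 16)])
        assert detect_alerts(t, 4).severe_unchanging

    def test_both_early_missed_yields_nonadherence_not_severe_flag(self):
        t = make_timeline(22, 2, [(2, None, None), (4, None, None)])
        a = detect_alerts(t, 4)
        assert a.nonadherent and not a.severe_unchanging

    def test_band_constant_timeline_raises_nothing(self):
        followups = [(w, 7, 2) for w in SCHEDULE_WEEKS]
        t = make_timeline(7, 2, followups)
        for w in SCHEDULE_WEEKS:
            assert not detect_alerts(t, w).any

    def test_alerts_depend_on_bands_not_totals(self):
        # Totals perturbed within the same band change no alert.
        t1 = make_timeline(12, 2, [(2, 10, 0), (4, 19, 4)])
        t2 = make_timeline(12, 2, [(2, 15, 2), (4, 11, 3)])
        for w in (2, 4):
            assert detect_alerts(t1, w) == detect_alerts(t2, w)

    def test_alert_truth_table_over_band_pairs(self):
        """Exhaustive (reference band, current band) enumeration per instrument:
        improvement iff current < reference, deterioration iff current > reference."""
        for ref, cur in itertools.product(B, B):
            # Depression moves; anxiety pinned at MILD to keep the baseline positive.
            t = make_timeline(
                PHQ_BAND_TOTAL[ref],
                GAD_BAND_TOTAL[1],
                [(2, PHQ_BAND_TOTAL[cur], GAD_BAND_TOTAL[1])],
            )
            a = detect_alerts(t, 2)
            assert a.improvement == (cur < ref)
            assert a.deterioration == (cur > ref)
            # Anxiety moves; depression pinned at MILD.
            t = make_timeline(
                PHQ_BAND_TOTAL[1],
                GAD_BAND_TOTAL[ref],
                [(2, PHQ_BAND_TOTAL[1], GAD_BAND_TOTAL[cur])],
            )
            a = detect_alerts(t, 2)
            assert a.improvement == (cur < ref)
            assert a.deterioration == (cur > ref)


class TestLastAssessment:
    def test_max_completed_week(self):
        t = make_timeline(12, 2, [(2, 12, 2), (4, None, None), (6, 9, 2), (10, 8, 2)])
        assert last_assessment(t).week == 10

    def test_single_completion(self):
        t = make_timeline(12, 2, [(2, 9, 2)])
        assert last_assessment(t).week == 2

    def test_non_completer_signalled(self):
        t = make_timeline(12, 2, [(2, None, None)])
        with pytest.raises(NonCompleterError):
            last_assessment(t)


class TestOutcomeClasses:
    def test_remitter_both_nil_minimal(self):
        assert classify_remitter(make_timeline(7, 7, [(18, 3, 2)]))

    def test_not_remitter_if_one_instrument_symptomatic(self):
        assert not classify_remitter(make_timeline(7, 7, [(18, 3, 6)]))

    def test_responder_drop_on_either(self):
        assert classify_responder(make_timeline(12, 2, [(18, 7, 2)]))
        assert classify_responder(make_timeline(7, 16, [(18, 7, 12)]))

    def test_not_responder_when_bands_static(self):
        assert not classify_responder(make_timeline(7, 7, [(18, 8, 6)]))

    def test_worsened_rise_on_either(self):
        assert classify_worsened(make_timeline(7, 2, [(18, 12, 2)]))

    def test_responder_and_worsened_can_co_occur(self):
        t = make_timeline(12, 7, [(18, 7, 12)])
        assert classify_responder(t) and classify_worsened(t)

    def test_worsened_any_point_variant(self):
        # Worse at week 2, recovered by week 4.
        t = make_timeline(7, 2, [(2, 12, 2), (4, 7, 2)])
        assert not classify_worsened(t)
        assert classify_worsened(t, at_any_point=True)

    def test_outcomes_judged_at_last_not_best(self):
        t = make_timeline(12, 2, [(2, 4, 2), (4, 12, 2)])
        assert not classify_responder(t)

    def test_remitter_implies_responder_exhaustive(self):
        """Over every positive baseline band pair and every last-assessment
        band pair: a remitter is always also a responder (the baseline has a
        symptomatic instrument, which must have dropped to nil-minimal)."""
        for b_phq, b_gad in itertools.product(B, B):
            if max(b_phq, b_gad) == B.NIL_MINIMAL:
                continue  # not monitored
            for l_phq, l_gad in itertools.product(B, B):
                t = make_timeline(
                    PHQ_BAND_TOTAL[b_phq],
                    GAD_BAND_TOTAL[b_gad],
                    [(18, PHQ_BAND_TOTAL[l_phq], GAD_BAND_TOTAL[l_gad])],
                )
                if classify_remitter(t):
                    assert classify_responder(t)
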
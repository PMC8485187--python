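"""Cohort analytics: summaries, NNS, concordance, outcome rates, effect size."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from helpers import make_record, make_timeline
from stepscreen import (
    Proportion,
    SeverityBand,
    cohen_d,
    concordance,
    nns,
    remission_response_rates,
    round_half_up,
    summarize_cohort,
    triage,
)
from stepscreen.analytics import PatientTreatmentRecord
from stepscreen.errors import AnalyticsError


class TestProportion:
    def test_retains_count_pair(self):
        p = Proportion(1428, 3314)
        assert p.pct(2) == 43.09
        assert str(p) == "1428/3314"

    def test_rounding_is_half_up(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(17.685, 2) == 17.69

    def test_invalid_pairs_rejected(self):
        with pytest.raises(AnalyticsError):
            Proportion(5, 3)


class TestSummarize:
    def test_single_negative_patient(self):
        s = summarize_cohort([triage(make_record(2, 2))], 1, 1)
        assert s.detection_rate == Proportion(0, 1)

    def test_empty_cohort_rejected(self):
        with pytest.raises(AnalyticsError):
            summarize_cohort([], 0, 0)

    def test_cascade_order_enforced(self):
        with pytest.raises(AnalyticsError):
            summarize_cohort([triage(make_record(2, 2))], 1, 0)

    def test_histogram_partitions_cohort(self):
        results = [triage(make_record(p, g)) for p, g in [(2, 2), (7, 2), (12, 16), (22, 2)]]
        s = summarize_cohort(results, 4, 4)
        assert sum(s.band_histogram.values()) == 4
        assert s.band_histogram[SeverityBand.SEVERE] == 2  # max-band combination

    def test_comorbidity_crosstab(self):
        results = [triage(make_record(p, g)) for p, g in [(7, 2), (2, 7), (12, 12)]]
        s = summarize_cohort(results, 3, 3)
        assert s.comorbidity[SeverityBand.MILD]["depression_only"] == 1
        assert s.comorbidity[SeverityBand.MILD]["anxiety_only"] == 1
        assert s.comorbidity[SeverityBand.MODERATE]["both"] == 1

    def test_observed_rate_matches_binomial_sampling(self):
        """A synthetic cohort drawn at a configured prevalence lands within
        3 binomial SEs of it."""
        rng = np.random.default_rng(11)
        p, n = 0.40, 2000
        draws = rng.random(n) < p
        results = [triage(make_record(7 if d else 2, 2, pid=f"x{i}")) for i, d in enumerate(draws)]
        s = summarize_cohort(results, n, n)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(s.detection_rate.value - p) <= 3 * se


class TestNNS:
    def test_study_values(self):
        r = nns(335, 5138)
        assert round_half_up(r.nns, 1) == 15.3
        assert round_half_up(r.ci_low, 1) == 13.9
        assert round_half_up(r.ci_high, 1) == 17.1
        assert r.formatted() == "15.3 (95% CI 13.9-17.1)"

    def test_degenerate_everyone_identified(self):
        assert nns(50, 50).nns == 1.0

    def test_inverse_of_one_percent(self):
        assert nns(1, 100).nns == 100.0

    def test_zero_identified_rejected(self):
        with pytest.raises(AnalyticsError):
            nns(0, 100)

    def test_wald_against_normal_quantile_oracle(self):
        """Brute-force Wald arithmetic at small n agrees with the library path."""
        k, n, alpha = 7, 120, 0.05
        ar = k / n
        z = norm.ppf(1 - alpha / 2)
        half = z * math.sqrt(ar * (1 - ar) / n)
        r = nns(k, n, alpha=alpha)
        assert r.ci_low == pytest.approx(1 / (ar + half), rel=1e-12)
        assert r.ci_high == pytest.approx(1 / (ar - half), rel=1e-12)

    def test_wilson_alternative_differs(self):
        wald = nns(335, 5138)
        wilson = nns(335, 5138, ci_method="wilson")
        assert wilson.ci_method == "wilson"
        assert round_half_up(wilson.ci_low, 1) == 13.8  # narrower than Wald's 13.9
        assert wald.ci_low != wilson.ci_low

    def test_monotone_in_identified_count(self):
        values = [nns(k, 5000).nns for k in range(10, 400, 25)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_ci_contains_point_and_tightens_with_n(self):
        narrow = nns(65, 1000)
        wide = nns(650, 10000)
        for r in (narrow, wide):
            assert r.ci_low <= r.nns <= r.ci_high
        assert (wide.ci_high - wide.ci_low) < (narrow.ci_high - narrow.ci_low)


def _treatment_record(pid, rec=frozenset(), rx=None, used=None):
    return PatientTreatmentRecord(pid, frozenset(rec), rx, used)


class TestConcordance:
    def test_no_overlap_data_gives_empty_uptake_without_division(self):
        records = [_treatment_record(f"p{i}") for i in range(5)]
        table = concordance(records)
        assert table.n_with_rx == 0 and table.n_with_both == 0
        assert table.uptake_digital.denominator == 0

    def test_uptake_conditioned_on_prescribed_group(self):
        from stepscreen import Treatment as T

        records = []
        for i in range(52):
            used = frozenset({T.WEB_SELF_HELP}) if i < 35 else frozenset()
            records.append(
                _treatment_record(f"d{i}", rx=frozenset({T.WEB_SELF_HELP}), used=used)
            )
        table = concordance(records)
        assert table.uptake_digital == Proportion(35, 52)
        assert table.uptake_digital.pct(0) == 67

    def test_consider_categories_count_as_recommended(self):
        from stepscreen import Treatment as T

        records = [
            _treatment_record(
                "p0",
                rec={T.PSYCHOLOGIST, T.MEDICATION, T.PSYCHIATRIST_CONSIDER},
                rx=frozenset({T.MEDICATION}),
            )
        ]
        table = concordance(records)
        assert table.recommended[T.PSYCHIATRIST].numerator == 1
        assert table.recommended_high_intensity.numerator == 1


class TestRemissionResponse:
    def test_band_constant_cohort_has_zero_responders(self):
        tls = [make_timeline(7, 7, [(2, 7, 7)], pid=f"p{i}") for i in range(10)]
        rates = remission_response_rates(tls)
        assert rates.responder_rate == Proportion(0, 10)

    def test_non_completers_excluded_from_denominator(self):
        tls = [
            make_timeline(12, 2, [(2, 7, 2)], pid="a"),
            make_timeline(12, 2, [(2, None, None)], pid="b"),
        ]
        rates = remission_response_rates(tls)
        assert rates.n_monitored == 2 and rates.n_completers == 1
        assert rates.responder_rate == Proportion(1, 1)

    def test_all_non_completers_rejected(self):
        tls = [make_timeline(12, 2, [], pid="a")]
        with pytest.raises(AnalyticsError):
            remission_response_rates(tls)


class TestCohenD:
    @pytest.mark.parametrize(
        "change, sd, expected",
        [(3.62, 6.20, 0.58), (1.45, 6.62, 0.22), (0.0, 5.0, 0.0)],
    )
    def test_standardised_change(self, change, sd, expected):
        assert round_half_up(cohen_d(change, sd), 2) == expected

    def test_sign_ignored(self):
        assert cohen_d(-3.62, 6.20) == cohen_d(3.62, 6.20)

    def test_zero_sd_rejected(self):
        with pytest.raises(AnalyticsError):
            cohen_d(1.0, 0.0)
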
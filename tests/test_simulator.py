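"""Synthetic cohort generator: determinism, cascade structure, calibration."""

import itertools
import math

import numpy as np
import pytest

from stepscreen import (
    SeverityBand,
    SimulationConfig,
    detect_alerts,
    parameter_recovery_report,
    simulate_cohort,
)
from stepscreen._compose import composition_counts, sample_composition
from stepscreen.instruments import score_gad7, score_phq9


def small_config(**overrides) -> SimulationConfig:
    base = dict(n_offered=300, seed=42)
    base.update(overrides)
    return SimulationConfig(**base)


class TestCompositionSampler:
    def test_counts_match_bruteforce_enumeration(self):
        """DP composition counts agree with exhaustive enumeration."""
        k, cap = 4, 3
        counts = composition_counts(k, cap)
        for t in range(k * cap + 1):
            brute = sum(
                1
                for combo in itertools.product(range(cap + 1), repeat=k)
                if sum(combo) == t
            )
            assert counts[k, t] == brute

    def test_sampled_compositions_valid(self):
        rng = np.random.default_rng(3)
        for total in (0, 5, 13, 21):
            parts = sample_composition(total, 7, 3, rng)
            assert sum(parts) == total
            assert all(0 <= p <= 3 for p in parts)

    def test_sampler_approximately_uniform(self):
        """Chi-square of sampled compositions against uniformity on a tiny case."""
        from scipy.stats import chisquare

        rng = np.random.default_rng(9)
        support = [c for c in itertools.product(range(3), repeat=3) if sum(c) == 3]
        draws = [sample_composition(3, 3, 2, rng) for _ in range(3500)]
        observed = [sum(1 for d in draws if d == s) for s in support]
        assert chisquare(observed).pvalue > 0.001

    def test_infeasible_total_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_composition(25, 8, 3, rng)


class TestDeterminism:
    def test_identical_config_identical_cohort(self):
        cfg = small_config()
        assert simulate_cohort(cfg) == simulate_cohort(cfg)

    def test_distinct_seeds_differ(self):
        a = simulate_cohort(small_config(seed=1))
        b = simulate_cohort(small_config(seed=2))
        assert a.records != b.records


class TestCascade:
    def test_counts_nested(self):
        for seed in range(5):
            c = simulate_cohort(small_config(seed=seed))
            assert c.n_positive <= c.n_eligible <= c.n_completed <= c.n_offered

    def test_zero_positivity_empties_monitoring(self):
        c = simulate_cohort(small_config(p_positive=0.0))
        assert c.n_positive == 0
        assert c.timelines == () and c.treatment_records == ()

    def test_degenerate_all_probabilities_one(self):
        c = simulate_cohort(
            small_config(
                n_offered=50,
                p_complete=1.0,
                p_eligible=1.0,
                p_positive=1.0,
                p_unidentified_given_positive=1.0,
            )
        )
        assert c.n_eligible == c.n_offered == c.n_positive == c.n_unidentified
        # Everyone newly identified -> NNS of 1.
        from stepscreen import nns

        assert nns(c.n_unidentified, c.n_offered).nns == 1.0


class TestGeneratedData:
    def test_items_rescore_to_target_bands(self):
        """Round-trip: generated item vectors re-score to totals whose
        bands match the triage results (including follow-ups)."""
        c = simulate_cohort(small_config())
        for record, result in zip(c.records, c.triage_results):
            assert score_phq9(record.phq9).band == result.phq_band
            assert score_gad7(record.gad7).band == result.gad_band
            assert record.phq9.items[8] == result.suicidality
        for t in c.timelines[:30]:
            for f in t.followups:
                if f.completed:
                    assert score_phq9(f.phq9).band == f.phq_band

    def test_positive_rate_within_3_binomial_se(self):
        cfg = SimulationConfig(n_offered=5138, seed=5)
        c = simulate_cohort(cfg)
        p = cfg.p_positive
        se = math.sqrt(p * (1 - p) / c.n_eligible)
        assert abs(c.n_positive / c.n_eligible - p) <= 3 * se

    def test_unidentified_patients_have_no_contact_flags(self):
        c = simulate_cohort(small_config())
        for record, result in zip(c.records, c.triage_results):
            if result.previously_unidentified:
                assert not record.prior_gp_mh_contact
                assert not record.current_visit_mh


class TestTimelineModel:
    def test_total_dropout_forces_nonadherence(self):
        c = simulate_cohort(small_config(p_never_engage=1.0))
        t = next(iter(c.timelines))
        assert not any(f.completed for f in t.followups)
        if t.scheduled_weeks()[:2] == (2, 4):
            assert detect_alerts(t, 4).nonadherent

    def test_flat_noiseless_trajectory_raises_no_band_alerts(self):
        flat = {"slope_mean": 0.0, "slope_sd": 0.0, "noise_sd": 0.0}
        c = simulate_cohort(
            small_config(
                phq_trajectory=flat,
                gad_trajectory=flat,
                p_never_engage=0.0,
                dropout_hazard=0.0,
                intermittent_miss=0.0,
                optout_hazard=0.0,
            )
        )
        for t in c.timelines:
            for w in t.scheduled_weeks():
                a = detect_alerts(t, w)
                assert not a.improvement and not a.deterioration

    def test_negative_slope_cohort_responds_more_than_worsens(self):
        from stepscreen import remission_response_rates

        cfg = SimulationConfig(n_offered=2500, seed=8, p_never_engage=0.2)
        c = simulate_cohort(cfg)
        rates = remission_response_rates(list(c.timelines))
        assert rates.responder_rate.value > rates.worsened_rate.value


class TestParameterRecovery:
    def test_truths_recovered_at_small_scale(self):
        cfg = SimulationConfig(n_offered=1500, seed=13)
        report = parameter_recovery_report(cfg, n_reps=12)
        det = report.metrics["detection_rate"]
        unid = report.metrics["unidentified_fraction"]
        assert det.within_3se and unid.within_3se

    def test_doubling_n_shrinks_mc_error(self):
        small = parameter_recovery_report(SimulationConfig(n_offered=600, seed=21), 10)
        large = parameter_recovery_report(SimulationConfig(n_offered=2400, seed=21), 10)
        # sqrt-n scaling: quadrupling n should roughly halve the SD.
        ratio = large.metrics["detection_rate"].sd / small.metrics["detection_rate"].sd
        assert ratio < 0.85
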
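import math

import numpy as np
import pytest

import cardiocea as cc
from cardiocea.markov_engine import (
    DEAD_CVD,
    DEAD_OTHER,
    DISEASE_FREE,
    HF_Y1,
    MOD_SEQ,
    EngineContext,
    cycle_event_probabilities,
    normalize_competing,
    rate_to_prob,
    severity_order,
)

from conftest import flat_incidence


class TestRateToProb:
    def test_zero_rate(self):
        assert rate_to_prob(0.0) == 0.0

    def test_inverse_of_log_transform(self):
        assert rate_to_prob(0.0943) == pytest.approx(0.09, abs=5e-4)

    def test_monotone_in_rate(self):
        assert rate_to_prob(0.05) < rate_to_prob(0.10)

    def test_negative_rate_is_fatal(self):
        with pytest.raises(ValueError):
            rate_to_prob(-0.01)


class TestSeverityOrder:
    def test_total_order(self):
        assert (
            severity_order("severe_stroke_sequelae")
            > severity_order("moderate_stroke_sequelae")
            > severity_order("heart_failure")
            > severity_order("post_ami")
            == severity_order("post_angina")
            == severity_order("post_stroke_no_sequelae")
            > severity_order("disease_free")
        )

    def test_dead_states_outside_the_order(self):
        with pytest.raises(ValueError):
            severity_order("dead_cvd")

    def test_sequelae_patient_reverts_after_infarction(self, params):
        """An AMI in a stroke-sequelae patient adds its costs and risks once,
        then the patient is again governed by the sequelae state."""
        ctx = EngineContext(params, "male")
        branches = ctx.resolve_event("ami", "moderate_stroke_sequelae", age=75)
        alive_dests = {d for d, p, c in branches if d < DEAD_CVD and p > 0}
        # every nonfatal path without a worse outcome ends back in the
        # sequelae state, never in the milder post-AMI state
        assert MOD_SEQ in alive_dests
        from cardiocea.markov_engine import POST_AMI
        assert POST_AMI not in alive_dests
        # AMI treatment cost is charged on every branch
        assert all(c >= params.cost("stemi_event") for _, p, c in branches if p > 0)

    def test_heart_failure_does_not_displace_sequelae(self, params):
        ctx = EngineContext(params, "male")
        branches = ctx.resolve_event("heart_failure_event", "moderate_stroke_sequelae", age=70)
        dests = {d for d, p, _ in branches if p > 0}
        assert dests == {DEAD_CVD, MOD_SEQ}  # no transition into the HF state


class TestNormalizeCompeting:
    def test_no_rescaling_needed(self):
        events, residual = normalize_competing({"a": 0.2, "b": 0.3})
        assert events == {"a": 0.2, "b": 0.3}
        assert residual == pytest.approx(0.5)

    def test_rescaling_branch(self):
        events, residual = normalize_competing({"a": 0.8, "b": 0.6})
        assert events["a"] == pytest.approx(0.8 / 1.4)
        assert events["b"] == pytest.approx(0.6 / 1.4)
        assert residual == 0.0

    def test_empty_map(self):
        events, residual = normalize_competing({})
        assert events == {} and residual == 1.0


class TestCycleEventProbabilities:
    def test_disease_free_passthrough(self, params):
        rate = params.baseline_rates.rate("male", 70, "ami")
        probs = cycle_event_probabilities(params, DISEASE_FREE, "male", 70)
        assert probs["ami"] == pytest.approx(rate_to_prob(rate), rel=1e-12)

    def test_first_year_stroke_outcome_distribution(self, params):
        """The cycle of a stroke carries the printed first-year risks:
        death 0.338, moderate sequelae 0.072, severe sequelae 0.169."""
        ctx = EngineContext(params, "male")
        branches = ctx.resolve_event("stroke", "disease_free", age=60)
        by_dest = {}
        for d, p, _ in branches:
            by_dest[d] = by_dest.get(d, 0.0) + p
        from cardiocea.markov_engine import POST_STROKE, SEV_SEQ
        assert by_dest[DEAD_CVD] == pytest.approx(0.338)
        assert by_dest[MOD_SEQ] == pytest.approx(0.072)
        assert by_dest[SEV_SEQ] == pytest.approx(0.169)
        assert by_dest[POST_STROKE] == pytest.approx(1 - 0.338 - 0.072 - 0.169)

    def test_later_year_rr_multiplies_baseline(self):
        rate = -math.log(1 - 0.01)  # annual probability exactly 0.01
        ps = cc.load_parameter_set().replace(baseline_rates=flat_incidence(stroke=rate))
        from cardiocea.markov_engine import POST_STROKE
        probs = cycle_event_probabilities(ps, POST_STROKE, "male", 70)
        assert probs["stroke"] == pytest.approx(0.01 * 2.82, rel=1e-12)

    def test_hf_tunnel_year_selects_mortality_band(self, params):
        from cardiocea.markov_engine import HF_Y2, HF_Y3P
        base = rate_to_prob(params.baseline_rates.rate("male", 70, "cvd_death"))
        p2 = cycle_event_probabilities(params, HF_Y1, "male", 70)["cvd_death"]
        p3 = cycle_event_probabilities(params, HF_Y2, "male", 70)["cvd_death"]
        pl = cycle_event_probabilities(params, HF_Y3P, "male", 70)["cvd_death"]
        assert p2 == pytest.approx(base * 5.05, rel=1e-12)
        assert p3 == pytest.approx(base * 4.62, rel=1e-12)
        assert pl == pytest.approx(base * 2.13, rel=1e-12)

    def test_absorbing_state_has_no_events(self, params):
        with pytest.raises(ValueError):
            cycle_event_probabilities(params, DEAD_OTHER, "male", 70)


class TestRunCohort:
    def test_no_event_horizon_credits_full_years(self):
        ps = cc.load_parameter_set(overrides={"discount_rate": 0.0}).replace(
            baseline_rates=flat_incidence()
        )
        trace = cc.run_cohort(ps, cc.PatientProfile("male", 98))
        assert trace.total_ly_undisc == pytest.approx(2.0, abs=1e-12)
        assert trace.occupancy[-1, DEAD_OTHER] == pytest.approx(1.0)

    def test_geometric_death_toy(self):
        """Annual death probability one half over three cycles gives
        1 + 1/2 + 1/4 expected undiscounted life years."""
        ps = cc.load_parameter_set(overrides={"discount_rate": 0.0}).replace(
            baseline_rates=flat_incidence(other_death=math.log(2))
        )
        trace = cc.run_cohort(ps, cc.PatientProfile("female", 97))
        assert trace.total_ly_undisc == pytest.approx(1.75, rel=1e-12)

    def test_treatment_with_protective_rrs_extends_life(self, params, male70):
        none = cc.run_cohort(params, male70)
        treated = cc.run_cohort(params, male70, cc.Strategy(drugs=("ccb",)))
        assert treated.total_ly_undisc >= none.total_ly_undisc

    def test_raising_event_rates_never_extends_life(self, params, male70):
        worse = params.replace(
            baseline_rates=params.baseline_rates.uniformly_scaled(1.5)
        )
        assert (
            cc.run_cohort(worse, male70).total_ly_undisc
            < cc.run_cohort(params, male70).total_ly_undisc
        )

    def test_dead_occupancy_nondecreasing(self, params):
        trace = cc.run_cohort(params, cc.PatientProfile("female", 40))
        dead = trace.occupancy[:, DEAD_CVD] + trace.occupancy[:, DEAD_OTHER]
        assert np.all(np.diff(dead) >= -1e-12)

    def test_trace_export_has_one_row_per_cycle(self, params, male70):
        df = cc.run_cohort(params, male70).to_frame()
        assert len(df) == 30
        assert {"age", "cycle_cost_disc", "cycle_ly_disc"} <= set(df.columns)


class TestMicrosim:
    def test_degenerate_certain_death_matches_cohort_exactly(self):
        ps = cc.load_parameter_set(overrides={"discount_rate": 0.0}).replace(
            baseline_rates=flat_incidence(other_death=50.0)  # probability 1 in float
        )
        profile = cc.PatientProfile("male", 98)
        cohort = cc.run_cohort(ps, profile)
        micro = cc.run_microsim(ps, profile, n=1, seed=0)
        assert micro.ly_undisc == cohort.total_ly_undisc == 1.0

    def test_geometric_toy_agreement(self):
        ps = cc.load_parameter_set(overrides={"discount_rate": 0.0}).replace(
            baseline_rates=flat_incidence(other_death=math.log(2))
        )
        profile = cc.PatientProfile("male", 97)
        micro = cc.run_microsim(ps, profile, n=50_000, seed=11)
        se = math.sqrt(0.6875 / 50_000)  # var of the 1+Bern+Bern·Bern chain
        assert abs(micro.ly_undisc - 1.75) < 3 * se

    def test_fixed_seed_reproducible(self, params, male70):
        a = cc.run_microsim(params, male70, n=2_000, seed=42)
        b = cc.run_microsim(params, male70, n=2_000, seed=42)
        assert a == b
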
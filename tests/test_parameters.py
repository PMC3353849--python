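import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cardiocea as cc
from cardiocea.parameters import DistributionSpec, distribution_from_estimate


class TestPackagedTables:
    """The packaged fixtures must match the source tables exactly."""

    def test_first_year_stroke_case_fatality(self, params):
        row = next(
            r for r in params.first_year
            if r.primary_event == "stroke" and r.secondary_event == "death"
        )
        assert row.probability == 0.338
        assert (row.ci_low, row.ci_high) == (0.315, 0.361)

    @pytest.mark.parametrize(
        "primary,secondary,sex,age,expected",
        [
            ("stroke", "moderate_sequelae", None, None, 0.072),
            ("stroke", "severe_sequelae", None, None, 0.169),
            ("ami", "death", None, 45, 0.04),
            ("ami", "death", None, 65, 0.09),
            ("ami", "death", None, 75, 0.20),
            ("ami", "death", None, 85, 0.38),
            ("angina", "cvd_death", "male", None, 0.0108),
            ("angina", "cvd_death", "female", None, 0.0134),
            ("reinfarction", "death", None, None, 0.242),
            ("primary_heart_failure", "death", "female", None, 0.163),
        ],
    )
    def test_first_year_lookups(self, params, primary, secondary, sex, age, expected):
        assert params.first_year_prob(primary, secondary, sex=sex, age=age) == expected

    def test_six_month_stroke_row_subsumes_in_hospital(self, params):
        # both windows are printed for stroke after infarction; the engine
        # must use the larger six-month value alone
        assert params.first_year_prob("nonstemi", "stroke") == 0.018
        assert params.first_year_prob("stemi", "stroke") == 0.021

    @pytest.mark.parametrize(
        "state,event,sex,age,band,expected",
        [
            ("post_stroke_no_sequelae", "stroke", None, None, None, 2.82),
            ("post_ami", "angina", None, None, None, 21.7),
            ("post_ami", "death", None, 50, None, 3.55),
            ("post_ami", "death", None, 75, None, 1.00),
            ("post_angina", "ami", "male", None, None, 3.88),
            ("post_angina", "ami", "female", None, None, 1.17),
            ("heart_failure", "death", "male", None, "second", 5.05),
            ("heart_failure", "death", "female", None, "third", 7.61),
            ("heart_failure", "death", "male", None, "later", 2.13),
            ("heart_failure", "hf_worsening", None, None, None, 9.58),
            ("severe_stroke_sequelae", "death", None, None, None, 3.0),
        ],
    )
    def test_later_year_lookups(self, params, state, event, sex, age, band, expected):
        assert params.later_rr(state, event, sex=sex, age=age, year_band=band) == expected

    @pytest.mark.parametrize(
        "comparison,outcome,variant,expected",
        [
            ("ace_vs_ccb", "heart_failure", "african_american_excluded", 0.86),
            ("ace_vs_ccb", "stroke", "african_american_excluded", 1.04),
            ("ace_vs_ccb", "stroke", "all_included", 1.13),
            ("diuretic_vs_ace", "angina", "all_included", 0.91),
            ("diuretic_vs_ace", "total_mortality", "african_american_excluded", 1.04),
        ],
    )
    def test_treatment_effect_lookups(self, params, comparison, outcome, variant, expected):
        assert params.effect(comparison, outcome, variant).rr == expected

    @pytest.mark.parametrize(
        "label,expected",
        [
            ("severe_stroke_sequelae_year", 99_875),
            ("stroke_event", 23_546),
            ("cardiac_death_hospital", 5_169),
            ("thiazide_year", 20),
            ("gp_visits_thiazide_first_year", 195),
        ],
    )
    def test_cost_lookups(self, params, label, expected):
        assert params.cost(label) == expected


class TestLoader:
    def test_override_discount_rate(self):
        ps = cc.load_parameter_set(overrides={"discount_rate": 0.0})
        assert ps.discount_rate == 0.0
        assert ps.threshold == 62_000.0  # everything else untouched

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError, match="unknown override"):
            cc.load_parameter_set(overrides={"no_such_setting": 1})

    def test_missing_table_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="first_year.csv"):
            cc.load_parameter_set(tmp_path)

    def test_out_of_range_probability_is_fatal(self, tmp_path, params):
        params.save(tmp_path)
        fy = (tmp_path / "first_year.csv").read_text()
        (tmp_path / "first_year.csv").write_text(fy.replace("0.338", "1.338"))
        with pytest.raises(ValueError, match="1.338"):
            cc.load_parameter_set(tmp_path)

    def test_unknown_state_label_is_fatal(self, tmp_path, params):
        params.save(tmp_path)
        ly = (tmp_path / "later_year.csv").read_text()
        (tmp_path / "later_year.csv").write_text(ly.replace("post_ami", "post_mi"))
        with pytest.raises(ValueError):
            cc.load_parameter_set(tmp_path)

    def test_round_trip(self, tmp_path, params):
        params.save(tmp_path)
        reloaded = cc.load_parameter_set(tmp_path)
        for name, df in params.to_frames().items():
            other = reloaded.to_frames()[name]
            assert df.reset_index(drop=True).equals(other.reset_index(drop=True)), name
        assert np.array_equal(
            params.baseline_rates.to_frame()["rate"],
            reloaded.baseline_rates.to_frame()["rate"],
        )

    def test_cost_uncertainty_cv_attaches_gamma(self):
        ps = cc.load_parameter_set(overrides={"cost_uncertainty_cv": 0.2})
        item = next(c for c in ps.costs if c.label == "stroke_event")
        assert item.spec.family == "gamma"
        assert item.spec.mean() == pytest.approx(item.value, rel=1e-12)


class TestDistributionFromEstimate:
    def test_beta_from_stroke_case_fatality(self):
        spec = distribution_from_estimate(0.338, 0.315, 0.361, "beta")
        alpha, beta = spec.params
        assert alpha == pytest.approx(548.9, abs=0.2)
        assert beta == pytest.approx(1075.0, abs=0.3)
        assert spec.mean() == pytest.approx(0.338, abs=1e-9)

    def test_lognormal_from_heart_failure_rr(self):
        spec = distribution_from_estimate(0.86, 0.80, 0.93, "lognormal")
        mu, sigma = spec.params
        assert mu == pytest.approx(math.log(0.86), abs=1e-12)
        assert sigma == pytest.approx(0.0384, abs=2e-4)
        assert spec.median() == pytest.approx(0.86, abs=1e-12)

    def test_gamma_matches_mean(self):
        spec = distribution_from_estimate(22_674, 18_000, 27_000, "gamma")
        assert spec.mean() == pytest.approx(22_674, rel=1e-9)

    @given(d=st.floats(min_value=1e-4, max_value=0.2))
    @settings(max_examples=50, deadline=None)
    def test_beta_symmetric_at_half(self, d):
        spec = distribution_from_estimate(0.5, 0.5 - d, 0.5 + d, "beta")
        alpha, beta = spec.params
        assert alpha == pytest.approx(beta, rel=1e-12)

    def test_zero_width_interval_degrades_to_fixed(self):
        assert distribution_from_estimate(0.3, 0.3, 0.3, "beta").family == "fixed"

    def test_beta_rejects_mean_outside_unit_interval(self):
        with pytest.raises(ValueError, match="mean in \\(0,1\\)"):
            distribution_from_estimate(1.5, 1.0, 2.0, "beta")

    @pytest.mark.parametrize(
        "mean,lo,hi,family",
        [(0.338, 0.315, 0.361, "beta"), (3_713, 2_000, 5_500, "gamma")],
    )
    def test_sampled_mean_matches(self, mean, lo, hi, family):
        spec = distribution_from_estimate(mean, lo, hi, family)
        rng = np.random.default_rng(12345)
        draws = np.array([spec.sample(rng, mean) for _ in range(100)])
        # vectorised draw for the large sample
        if family == "beta":
            draws = rng.beta(*spec.params, size=1_000_000)
        else:
            draws = rng.gamma(spec.params[0], spec.params[1], size=1_000_000)
        se = draws.std(ddof=1) / 1000
        assert abs(draws.mean() - mean) < 3 * se
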
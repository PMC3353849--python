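import numpy as np
import pytest

import cardiocea as cc
from cardiocea.markov_engine import PatientProfile
from cardiocea.psa import PSASampleSet, ceac, run_psa, sample_parameter_set
from cardiocea.treatment import Strategy

from conftest import all_fixed


@pytest.fixture(scope="module")
def small_setup(params):
    ps = params
    profiles = [PatientProfile("male", 70)]
    strategies = [Strategy(), Strategy(drugs=("ccb",)), Strategy(drugs=("thiazide",))]
    return ps, profiles, strategies


class TestSampling:
    def test_all_fixed_passthrough(self, params):
        frozen = all_fixed(params)
        rng = np.random.default_rng(0)
        sampled = sample_parameter_set(frozen, rng)
        assert [r.probability for r in sampled.first_year] == [
            r.probability for r in frozen.first_year
        ]
        assert [r.rr for r in sampled.effects] == [r.rr for r in frozen.effects]

    def test_same_seed_same_draws(self, params):
        a = sample_parameter_set(params, np.random.default_rng(5))
        b = sample_parameter_set(params, np.random.default_rng(5))
        assert [r.probability for r in a.first_year] == [r.probability for r in b.first_year]
        assert [r.rr for r in a.later_year] == [r.rr for r in b.later_year]

    def test_beta_draws_recover_estimate(self, params):
        row = next(
            r for r in params.first_year
            if r.primary_event == "stroke" and r.secondary_event == "death"
        )
        assert row.spec.family == "beta"
        rng = np.random.default_rng(99)
        draws = rng.beta(*row.spec.params, size=1_000_000)
        se = draws.std(ddof=1) / 1_000
        assert abs(draws.mean() - 0.338) < 3 * se

    def test_sampled_probabilities_stay_valid(self, params):
        rng = np.random.default_rng(3)
        for _ in range(20):
            sampled = sample_parameter_set(params, rng)
            sampled.validate()
            assert all(0 <= r.probability <= 1 for r in sampled.first_year)
            assert all(r.rr > 0 for r in sampled.later_year)

    def test_gamma_cost_variance_passes_through(self):
        ps = cc.load_parameter_set(overrides={"cost_uncertainty_cv": 0.2})
        item = next(c for c in ps.costs if c.label == "stroke_event")
        rng = np.random.default_rng(17)
        draws = np.array(
            [item.spec.sample(rng, item.value) for _ in range(200_000)]
        )
        # variance of a variance estimate: ~ var * sqrt(2/(n-1)) for the SD
        assert draws.var(ddof=1) == pytest.approx(item.spec.var(), rel=0.05)


class TestRunPsa:
    def test_single_fixed_iteration_collapses_to_deterministic(self, small_setup):
        ps, profiles, strategies = small_setup
        frozen = all_fixed(ps)
        samples = run_psa(frozen, profiles, strategies, n_iter=1, seed=0)
        direct = cc.run_cohort(frozen, profiles[0], strategies[1])
        assert samples.cost_disc[0, 0, 1] == pytest.approx(direct.total_cost_disc, rel=1e-12)
        assert samples.ly_disc[0, 0, 1] == pytest.approx(direct.total_ly_disc, rel=1e-12)

    def test_reproducible_for_fixed_seed(self, small_setup):
        ps, profiles, strategies = small_setup
        a = run_psa(ps, profiles, strategies, n_iter=20, seed=123)
        b = run_psa(ps, profiles, strategies, n_iter=20, seed=123)
        assert np.array_equal(a.cost_disc, b.cost_disc)
        assert np.array_equal(a.ly_disc, b.ly_disc)

    def test_every_iteration_covers_every_strategy(self, small_setup):
        ps, profiles, strategies = small_setup
        samples = run_psa(ps, profiles, strategies, n_iter=10, seed=1)
        assert samples.cost_disc.shape == (10, 1, 3)
        assert not np.isnan(samples.cost_disc).any()
        assert samples.failed_iterations == ()


def _handmade_samples():
    """Three iterations over two strategies with winners enumerable by hand.

    iter 0: A (10,000; 10.0) vs B (10,000; 10.0) -> exact tie at any threshold
    iter 1: A (10,000; 10.0) vs B (11,000; 10.5) -> B wins at 62,000
            (net benefit 10.323 vs 9.839); A wins at threshold 0 (cheaper)
    iter 2: A (10,000; 10.0) vs B (30,000; 10.1) -> A wins at 62,000
            (9.839 vs 9.616); B wins as the threshold grows unbounded
    """
    cost = np.array([[[10_000.0, 10_000.0]], [[10_000.0, 11_000.0]], [[10_000.0, 30_000.0]]])
    ly = np.array([[[10.0, 10.0]], [[10.0, 10.5]], [[10.0, 10.1]]])
    return PSASampleSet(
        profiles=(PatientProfile("male", 70),),
        strategies=(Strategy(label="A"), Strategy(drugs=("ccb",), label="B")),
        seed=0,
        cost_disc=cost,
        ly_disc=ly,
    )


class TestCeac:
    def test_hand_enumerated_winner_fractions(self):
        samples = _handmade_samples()
        table = ceac(samples, thresholds=np.array([62_000.0]))
        # tie in iteration 0 splits; A and B win one iteration each
        assert table.probability[0, 0] == pytest.approx((0.5 + 1.0) / 3)
        assert table.probability[0, 1] == pytest.approx((0.5 + 1.0) / 3)

    def test_columns_sum_to_one(self):
        samples = _handmade_samples()
        table = ceac(samples, thresholds=np.arange(0, 150_001, 2_500, dtype=float))
        assert np.allclose(table.probability.sum(axis=1), 1.0, atol=1e-9)

    def test_threshold_limits_select_cheapest_and_most_effective(self):
        samples = _handmade_samples()
        table = ceac(samples, thresholds=np.array([0.0, 1e12]))
        # threshold 0: cheapest wins (A in iters 1-2, tie split in iter 0)
        assert table.probability[0, 0] == pytest.approx((0.5 + 1.0 + 1.0) / 3)
        # unbounded threshold: most life years wins (B in iters 1-2)
        assert table.probability[1, 1] == pytest.approx((0.5 + 1.0 + 1.0) / 3)

    def test_single_strategy_always_wins(self):
        s = _handmade_samples()
        alone = PSASampleSet(
            profiles=s.profiles,
            strategies=s.strategies[:1],
            seed=0,
            cost_disc=s.cost_disc[:, :, :1],
            ly_disc=s.ly_disc[:, :, :1],
        )
        table = ceac(alone, thresholds=np.array([0.0, 62_000.0, 1e9]))
        assert np.all(table.probability == 1.0)

    def test_identical_strategies_split_evenly(self):
        s = _handmade_samples()
        twin = PSASampleSet(
            profiles=s.profiles,
            strategies=s.strategies,
            seed=0,
            cost_disc=np.repeat(s.cost_disc[:, :, :1], 2, axis=2),
            ly_disc=np.repeat(s.ly_disc[:, :, :1], 2, axis=2),
        )
        table = ceac(twin, thresholds=np.array([30_000.0]))
        assert np.allclose(table.probability, 0.5)

    def test_dominating_strategy_has_probability_one(self):
        s = _handmade_samples()
        dominated = PSASampleSet(
            profiles=s.profiles,
            strategies=s.strategies,
            seed=0,
            cost_disc=np.concatenate(
                [s.cost_disc[:, :, :1], s.cost_disc[:, :, :1] + 1_000], axis=2
            ),
            ly_disc=np.concatenate(
                [s.ly_disc[:, :, :1], s.ly_disc[:, :, :1] - 0.1], axis=2
            ),
        )
        table = ceac(dominated, thresholds=np.arange(0, 100_001, 10_000, dtype=float))
        assert np.all(table.probability[:, 0] == 1.0)
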
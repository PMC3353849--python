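"""Probabilistic sensitivity analysis and acceptability curves.

Parameter (second-order) uncertainty is propagated by Monte Carlo: each
iteration draws one value for every uncertain input — beta for
probabilities, log-normal for relative risks, gamma for costs when enabled
— evaluates every strategy on the *same* sampled parameter set (common
random parameters, so decision uncertainty is not inflated by independent
noise across strategies), and records lifetime discounted cost and life
years. The cost-effectiveness acceptability curve (CEAC) then reports, per
willingness-to-pay threshold, the fraction of iterations in which each
strategy has the highest net benefit ``ly - cost / threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .markov_engine import EngineContext, PatientProfile, run_cohort
from .parameters import ParameterSet
from .treatment import Strategy

__all__ = ["PSASampleSet", "CEACTable", "sample_parameter_set", "run_psa", "ceac"]

DEFAULT_THRESHOLDS = np.arange(0, 150_001, 2_500, dtype=float)


def sample_parameter_set(base: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """Draw one parameter set from the attached uncertainty distributions.

    Fixed-family inputs pass through unchanged; rows are visited in their
    table order so draws are reproducible for a given generator state.
    Sampled rows drop their confidence bounds (the bounds describe the
    estimate, not the draw).
    """
    first_year = tuple(
        r
        if r.spec.family == "fixed"
        else dc_replace(r, probability=r.spec.sample(rng, r.probability),
                        ci_low=None, ci_high=None)
        for r in base.first_year
    )
    later_year = tuple(
        r
        if r.spec.family == "fixed"
        else dc_replace(r, rr=r.spec.sample(rng, r.rr), ci_low=None, ci_high=None)
        for r in base.later_year
    )
    effects = tuple(
        r
        if r.spec.family == "fixed"
        else dc_replace(r, rr=r.spec.sample(rng, r.rr), ci_low=None, ci_high=None)
        for r in base.effects
    )
    costs = tuple(
        r if r.spec.family == "fixed" else dc_replace(r, value=r.spec.sample(rng, r.value))
        for r in base.costs
    )
    sampled = base.replace(
        first_year=first_year, later_year=later_year, effects=effects, costs=costs
    )
    return sampled


@dataclass
class PSASampleSet:
    """Per-iteration lifetime outcomes for every strategy and profile."""

    profiles: tuple[PatientProfile, ...]
    strategies: tuple[Strategy, ...]
    seed: int
    cost_disc: np.ndarray  # (n_iter, n_profiles, n_strategies)
    ly_disc: np.ndarray
    failed_iterations: tuple[int, ...] = ()

    @property
    def n_iter(self) -> int:
        return self.cost_disc.shape[0]

    def to_frame(self) -> pd.DataFrame:
        records = []
        for i in range(self.n_iter):
            for j, profile in enumerate(self.profiles):
                for k, strat in enumerate(self.strategies):
                    records.append(
                        {
                            "iteration": i,
                            "sex": profile.sex,
                            "start_age": profile.start_age,
                            "strategy": strat.label,
                            "cost_disc": self.cost_disc[i, j, k],
                            "ly_disc": self.ly_disc[i, j, k],
                        }
                    )
        return pd.DataFrame(records)

    def scatter_frame(self, baseline: Strategy, profile_index: int = 0) -> pd.DataFrame:
        """Incremental (cost, effect) pairs per iteration vs a baseline."""
        k0 = self.strategies.index(baseline)
        records = []
        for k, strat in enumerate(self.strategies):
            if k == k0:
                continue
            for i in range(self.n_iter):
                records.append(
                    {
                        "strategy": strat.label,
                        "iteration": i,
                        "ic": self.cost_disc[i, profile_index, k]
                        - self.cost_disc[i, profile_index, k0],
                        "ie": self.ly_disc[i, profile_index, k]
                        - self.ly_disc[i, profile_index, k0],
                    }
                )
        return pd.DataFrame(records)


def run_psa(
    base: ParameterSet,
    profiles: Sequence[PatientProfile],
    strategies: Sequence[Strategy],
    n_iter: int = 10_000,
    seed: int = 0,
) -> PSASampleSet:
    """Monte Carlo over parameter uncertainty.

    Every strategy and profile is evaluated on the same sampled parameter
    set within an iteration. An engine failure marks the iteration as
    failed (outcomes NaN) and the run continues.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    profiles = tuple(profiles)
    strategies = tuple(strategies)
    rng = np.random.default_rng(seed)
    cost = np.full((n_iter, len(profiles), len(strategies)), np.nan)
    ly = np.full_like(cost, np.nan)
    failed = []
    for i in range(n_iter):
        sampled = sample_parameter_set(base, rng)
        try:
            contexts = {}
            for j, profile in enumerate(profiles):
                ctx = contexts.get(profile.sex)
                if ctx is None:
                    ctx = contexts[profile.sex] = EngineContext(sampled, profile.sex)
                for k, strat in enumerate(strategies):
                    trace = run_cohort(sampled, profile, strat, ctx=ctx)
                    cost[i, j, k] = trace.total_cost_disc
                    ly[i, j, k] = trace.total_ly_disc
        except Exception:
            failed.append(i)
    return PSASampleSet(
        profiles=profiles,
        strategies=strategies,
        seed=seed,
        cost_disc=cost,
        ly_disc=ly,
        failed_iterations=tuple(failed),
    )


@dataclass
class CEACTable:
    thresholds: np.ndarray
    strategies: tuple[Strategy, ...]
    probability: np.ndarray  # (n_thresholds, n_strategies)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.probability, columns=[s.label for s in self.strategies]
        )
        df.insert(0, "threshold", self.thresholds)
        return df


def ceac(
    samples: PSASampleSet,
    thresholds: Optional[np.ndarray] = None,
    profile_index: int = 0,
) -> CEACTable:
    """Cost-effectiveness acceptability curves for one patient profile.

    Per threshold ``t`` and iteration, the winner maximises
    ``ly - cost / t`` (at ``t = 0``: the least-cost strategy); ties share
    the win equally, so each column of probabilities sums to one.
    """
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else np.asarray(thresholds, float)
    cost = samples.cost_disc[:, profile_index, :]
    ly = samples.ly_disc[:, profile_index, :]
    ok = ~np.isnan(cost).any(axis=1)
    cost, ly = cost[ok], ly[ok]
    if cost.shape[0] == 0:
        raise ValueError("no successful iterations")
    n_iter, n_strat = cost.shape
    probs = np.zeros((len(thresholds), n_strat))
    for ti, t in enumerate(thresholds):
        nb = -cost if t == 0 else ly - cost / t
        best = nb.max(axis=1, keepdims=True)
        winners = nb == best
        probs[ti] = (winners / winners.sum(axis=1, keepdims=True)).sum(axis=0) / n_iter
    return CEACTable(
        thresholds=thresholds,
        strategies=samples.strategies,
        probability=probs,
    )
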
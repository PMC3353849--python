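"""Model/Results interface over the cohort engine.

:class:`CvdPolicyModel` bundles a parameter set with the patient profiles
and treatment strategies to evaluate; ``fit()`` runs the deterministic
cohort model for every (profile, strategy) pair and returns a
:class:`CvdPolicyResults` carrying lifetime costs and life expectancies,
comparison tables and a ``summary()``. ``fit_psa()`` propagates parameter
uncertainty by Monte Carlo and returns a :class:`CvdPolicyPSAResults` with
acceptability curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import economics
from .calibration import CalibrationResult, calibrate_incidence
from .markov_engine import EngineContext, PatientProfile, run_cohort
from .parameters import ParameterSet, load_parameter_set
from .psa import CEACTable, PSASampleSet, ceac, run_psa
from .synthetic_data import generate_baseline_rates
from .treatment import DRUGS, Strategy

__all__ = [
    "CvdPolicyModel",
    "CvdPolicyResults",
    "CvdPolicyPSAResults",
    "default_profiles",
    "default_strategies",
]

NO_TREATMENT = Strategy()


def default_profiles() -> tuple[PatientProfile, ...]:
    """Men and women at ages 40, 50, 60 and 70."""
    return tuple(
        PatientProfile(sex=sex, start_age=age)
        for sex in ("male", "female")
        for age in (40, 50, 60, 70)
    )


def default_strategies() -> tuple[Strategy, ...]:
    """No treatment, the 5 monotherapies, 10 pairs and 10 triples."""
    out = [NO_TREATMENT]
    for k in (1, 2, 3):
        out.extend(Strategy(drugs=c) for c in combinations(DRUGS, k))
    return tuple(out)


class CvdPolicyModel:
    """Lifetime cost-effectiveness model for antihypertensive strategies.

    Parameters
    ----------
    params : ParameterSet, optional
        Model inputs; the packaged tables with synthetic baseline incidence
        are used when omitted.
    profiles : sequence of PatientProfile, optional
    strategies : sequence of Strategy, optional
    """

    def __init__(
        self,
        params: Optional[ParameterSet] = None,
        profiles: Optional[Sequence[PatientProfile]] = None,
        strategies: Optional[Sequence[Strategy]] = None,
    ):
        if params is None:
            params = load_parameter_set()
        if params.baseline_rates is None:
            params = params.replace(baseline_rates=generate_baseline_rates())
        self.params = params
        self.profiles = tuple(profiles) if profiles is not None else default_profiles()
        self.strategies = (
            tuple(strategies) if strategies is not None else default_strategies()
        )
        if len(set(self.profiles)) != len(self.profiles):
            raise ValueError("duplicate profiles")
        if len({s.label for s in self.strategies}) != len(self.strategies):
            raise ValueError("duplicate strategies")

    # ------------------------------------------------------------------

    def calibrate(
        self,
        targets: Mapping[tuple[str, int], float],
        tol: float = 1e-3,
        max_iter: int = 50,
        start_age: int = 40,
    ) -> tuple["CvdPolicyModel", CalibrationResult]:
        """Return a new model with baseline rates scaled to hit the CVD
        mortality targets, along with the calibration diagnostics."""
        result = calibrate_incidence(
            self.params, targets, tol=tol, max_iter=max_iter, start_age=start_age
        )
        calibrated = self.params.replace(
            baseline_rates=self.params.baseline_rates.scaled(result.scale_factors)
        )
        return CvdPolicyModel(calibrated, self.profiles, self.strategies), result

    def fit(self) -> "CvdPolicyResults":
        """Deterministic cohort run for every profile and strategy."""
        results: dict = {}
        for profile in self.profiles:
            ctx = EngineContext(self.params, profile.sex)
            for strategy in self.strategies:
                trace = run_cohort(self.params, profile, strategy, ctx=ctx)
                results[(profile, strategy.label)] = economics.StrategyResult.from_trace(
                    trace, strategy, profile
                )
        return CvdPolicyResults(model=self, results=results)

    def fit_psa(
        self,
        n_iter: int = 10_000,
        seed: int = 0,
        profiles: Optional[Sequence[PatientProfile]] = None,
        strategies: Optional[Sequence[Strategy]] = None,
    ) -> "CvdPolicyPSAResults":
        """Probabilistic sensitivity analysis over the attached parameter
        distributions."""
        samples = run_psa(
            self.params,
            profiles if profiles is not None else self.profiles,
            strategies if strategies is not None else self.strategies,
            n_iter=n_iter,
            seed=seed,
        )
        return CvdPolicyPSAResults(model=self, samples=samples)


@dataclass
class CvdPolicyResults:
    """Lifetime outcomes per (profile, strategy) plus decision tables."""

    model: CvdPolicyModel
    results: dict

    def get(self, profile: PatientProfile, strategy: Strategy | str) -> economics.StrategyResult:
        label = strategy if isinstance(strategy, str) else strategy.label
        return self.results[(profile, label)]

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "sex": p.sex,
                "start_age": p.start_age,
                "strategy": label,
                "cost_disc": r.cost_disc,
                "cost_undisc": r.cost_undisc,
                "ly_disc": r.ly_disc,
                "ly_undisc": r.ly_undisc,
            }
            for (p, label), r in self.results.items()
        ]
        return pd.DataFrame(rows)

    def compare(
        self,
        strategy: Strategy | str,
        baseline: Strategy | str,
        profile: PatientProfile,
        threshold: Optional[float] = None,
        discounted: bool = True,
    ) -> economics.ComparisonResult:
        threshold = threshold if threshold is not None else self.model.params.threshold
        return economics.compare(
            self.get(profile, strategy),
            self.get(profile, baseline),
            threshold,
            discounted=discounted,
        )

    def rank(
        self,
        baseline: Strategy,
        profile: PatientProfile,
        strategies: Optional[Sequence[Strategy]] = None,
        threshold: Optional[float] = None,
    ) -> list[economics.ComparisonResult]:
        threshold = threshold if threshold is not None else self.model.params.threshold
        strategies = strategies if strategies is not None else self.model.strategies
        pool = [self.get(profile, s) for s in strategies]
        if not any(s == baseline for s in strategies):
            pool.append(self.get(profile, baseline))
        return economics.rank_strategies(pool, baseline, threshold)

    def inhb_table(
        self,
        strategies: Sequence[Strategy],
        baseline: Strategy,
        threshold: Optional[float] = None,
        discounted: bool = True,
    ) -> pd.DataFrame:
        """INHB of each strategy vs a common baseline; one row per strategy,
        one column per (sex, start age)."""
        threshold = threshold if threshold is not None else self.model.params.threshold
        data = {}
        for profile in self.model.profiles:
            col = (profile.sex, profile.start_age)
            data[col] = {
                s.label: self.compare(
                    s, baseline, profile, threshold, discounted=discounted
                ).inhb
                for s in strategies
                if s != baseline
            }
        df = pd.DataFrame(data)
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["sex", "start_age"])
        df.index.name = f"inhb_vs_{baseline.label}"
        return df

    def summary(self) -> str:
        """Readable overview: lifetime outcomes and monotherapy INHBs."""
        lines = ["Lifetime cohort results (per patient)", "=" * 60]
        frame = self.frame()
        lines.append(
            frame.to_string(
                index=False,
                float_format=lambda v: f"{v:,.3f}",
            )
        )
        monos = [s for s in self.model.strategies if len(s.drugs) == 1]
        if monos and any(s == NO_TREATMENT for s in self.model.strategies):
            lines += [
                "",
                f"INHB vs no treatment at T = {self.model.params.threshold:,.0f} euro/LY",
                "-" * 60,
                self.inhb_table(monos, NO_TREATMENT).to_string(
                    float_format=lambda v: f"{v:.2f}"
                ),
            ]
        return "\n".join(lines)


@dataclass
class CvdPolicyPSAResults:
    model: CvdPolicyModel
    samples: PSASampleSet

    def ceac(
        self,
        thresholds: Optional[np.ndarray] = None,
        profile: Optional[PatientProfile] = None,
    ) -> CEACTable:
        idx = 0 if profile is None else self.samples.profiles.index(profile)
        return ceac(self.samples, thresholds, profile_index=idx)

    def summary(self) -> str:
        t = self.model.params.threshold
        table = self.ceac(thresholds=np.array([t]))
        probs = ", ".join(
            f"{s.label}: {p:.2f}"
            for s, p in zip(table.strategies, table.probability[0])
        )
        return (
            f"PSA with {self.samples.n_iter} iterations "
            f"({len(self.samples.failed_iterations)} failed)\n"
            f"P(most cost-effective) at T = {t:,.0f}: {probs}"
        )
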
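"""Calibration of baseline incidence to CVD-specific mortality targets.

The untreated model's CVD mortality (deaths from cardiovascular causes per
person-year, by sex and decade of age) should reproduce observed national
rates. Calibration searches per-(sex, decade) multiplicative factors on the
baseline CVD incidence rates — primary events and CVD death; the
event-conditional first- and later-year evidence tables are never rescaled
— using a ratio update ``factor <- factor * target / achieved`` until the
achieved mortality matches the targets.

This is a reconstruction of a calibration stage whose original procedure is
not published; the ratio search is the simplest method satisfying the
stated goal and converges quickly because band mortality is close to
proportional to the band's scaling factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .markov_engine import PatientProfile, run_cohort
from .parameters import ParameterSet

__all__ = ["CalibrationResult", "achieved_cvd_mortality", "calibrate_incidence"]

SEXES = ("male", "female")


def achieved_cvd_mortality(
    params: ParameterSet, start_age: int = 40
) -> dict[tuple[str, int], float]:
    """CVD deaths per person-year by (sex, decade band) from the untreated
    cohort model; bands are keyed by their starting age (40 = ages 40-49)."""
    out: dict[tuple[str, int], float] = {}
    for sex in SEXES:
        trace = run_cohort(params, PatientProfile(sex=sex, start_age=start_age))
        bands = (trace.ages // 10) * 10
        for band in np.unique(bands):
            mask = bands == band
            py = float(trace.ly_undisc[mask].sum())
            deaths = float(trace.cvd_deaths[mask].sum())
            if py > 0:
                out[(sex, int(band))] = deaths / py
    return out


@dataclass
class CalibrationResult:
    scale_factors: dict[tuple[str, int], float]
    achieved_rates: dict[tuple[str, int], float]
    targets: dict[tuple[str, int], float]
    iterations: int
    converged: bool
    max_rel_deviation: float
    history: list[float] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "sex": sex,
                "band": band,
                "scale_factor": f,
                "achieved": self.achieved_rates.get((sex, band)),
                "target": self.targets.get((sex, band)),
            }
            for (sex, band), f in sorted(self.scale_factors.items())
        ]
        return pd.DataFrame(rows)


def calibrate_incidence(
    params: ParameterSet,
    targets: Mapping[tuple[str, int], float],
    tol: float = 1e-3,
    max_iter: int = 50,
    start_age: int = 40,
) -> CalibrationResult:
    """Fit per-(sex, decade) scale factors so the untreated model reproduces
    the target CVD mortality rates.

    Non-convergence within ``max_iter`` returns a result with
    ``converged=False`` and the deviation trace rather than raising.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    targets = dict(targets)
    for key, value in targets.items():
        if value <= 0:
            raise ValueError(f"target for {key} must be positive")
    factors = {key: 1.0 for key in targets}
    base_rates = params.baseline_rates
    achieved: dict[tuple[str, int], float] = {}
    history: list[float] = []
    converged = False
    iterations = 0
    max_dev = np.inf
    for iterations in range(1, max_iter + 1):
        scaled = params.replace(baseline_rates=base_rates.scaled(factors))
        achieved = achieved_cvd_mortality(scaled, start_age=start_age)
        max_dev = max(
            abs(achieved[key] - targets[key]) / targets[key] for key in targets
        )
        history.append(max_dev)
        if max_dev <= tol:
            converged = True
            break
        for key in targets:
            if achieved.get(key, 0.0) > 0:
                factors[key] *= targets[key] / achieved[key]
    return CalibrationResult(
        scale_factors=factors,
        achieved_rates=achieved,
        targets=targets,
        iterations=iterations,
        converged=converged,
        max_rel_deviation=float(max_dev),
        history=history,
    )
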
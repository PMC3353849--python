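"""Synthetic age-/sex-specific baseline incidence of primary CVD events.

The cohort engine needs annual population rates of first-ever AMI, stroke,
angina, heart failure, CVD death and non-CVD death by sex and single year of
age. National registry curves of that kind are not redistributable, so this
module generates a registry-like stand-in: Gompertz hazards
``rate(age) = a * exp(b * (age - 40))`` per event, with a multiplicative
female/male ratio per event and optional seeded log-normal jitter. The
default parameters are a qualitative imitation of a Northern-European
population (incidence roughly doubling every 8-10 years of age, male excess
for coronary events); they are synthetic and make no claim of numerical
fidelity to any registry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EVENTS",
    "AGE_MIN",
    "AGE_MAX",
    "GompertzConfig",
    "DEFAULT_CONFIG",
    "IncidenceTable",
    "generate_baseline_rates",
    "generate_calibration_targets",
]

EVENTS = ("ami", "stroke", "angina", "heart_failure_event", "cvd_death", "other_death")
CVD_EVENTS = EVENTS[:-1]  # everything except other_death
AGE_MIN = 30
AGE_MAX = 100
SEXES = ("male", "female")


@dataclass(frozen=True)
class GompertzConfig:
    """Per-event hazard parameters: rate ``a`` at age 40 (male), log-slope
    ``b`` per year of age, and the female/male rate ratio."""

    a: float
    b: float
    female_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be positive")
        if self.b < 0:
            raise ValueError("b must be nonnegative")
        if self.female_ratio <= 0:
            raise ValueError("female_ratio must be positive")


# Defaults: male AMI excess, near-parity for stroke, mortality rising
# steeply with age. Chosen once as a plausible synthetic population.
DEFAULT_CONFIG: Mapping[str, GompertzConfig] = {
    "ami": GompertzConfig(0.0010, 0.085, 0.50),
    "stroke": GompertzConfig(0.0006, 0.090, 0.90),
    "angina": GompertzConfig(0.0012, 0.070, 0.80),
    "heart_failure_event": GompertzConfig(0.0004, 0.100, 0.80),
    "cvd_death": GompertzConfig(0.0003, 0.110, 0.70),
    "other_death": GompertzConfig(0.0012, 0.095, 0.85),
}


@dataclass
class IncidenceTable:
    """Annual event rates (per person-year) keyed by sex, age and event.

    Stored as dense arrays over ages ``AGE_MIN..AGE_MAX`` for fast lookup in
    the cycle loop.
    """

    rates: dict  # (sex, event) -> np.ndarray over ages AGE_MIN..AGE_MAX

    def rate(self, sex: str, age: int, event: str) -> float:
        age = min(max(int(age), AGE_MIN), AGE_MAX)
        return float(self.rates[(sex, event)][age - AGE_MIN])

    def scaled(self, factors: Mapping[tuple[str, int], float]) -> "IncidenceTable":
        """Return a copy with CVD-event rates multiplied by per-(sex, decade
        band) factors; ``other_death`` is never rescaled. Band keys are the
        decade start (e.g. 40 for ages 40-49); ages outside any supplied
        band keep factor 1."""
        new = {}
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
        for (sex, event), arr in self.rates.items():
            if event not in CVD_EVENTS:
                new[(sex, event)] = arr.copy()
                continue
            mult = np.ones_like(arr)
            for (fsex, band), f in factors.items():
                if fsex == sex:
                    mult[(ages >= band) & (ages < band + 10)] = f
            new[(sex, event)] = arr * mult
        return IncidenceTable(new)

    def uniformly_scaled(self, factor: float) -> "IncidenceTable":
        bands = {(s, b): factor for s in SEXES for b in range(AGE_MIN, AGE_MAX, 10)}
        return self.scaled(bands)

    def validate(self) -> None:
        for (sex, event), arr in self.rates.items():
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"invalid rate for ({sex}, {event})")
            probs = 1.0 - np.exp(-arr)
            if np.any(probs >= 1.0):
                age = AGE_MIN + int(np.argmax(probs >= 1.0))
                raise ValueError(
                    f"annual probability >= 1 for event {event!r} at age {age}"
                )

    def to_frame(self) -> pd.DataFrame:
        records = []
        for (sex, event), arr in sorted(self.rates.items()):
            for i, r in enumerate(arr):
                records.append(
                    {"sex": sex, "age": AGE_MIN + i, "event": event, "rate": r}
                )
        return pd.DataFrame(records)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IncidenceTable":
        rates = {}
        for (sex, event), grp in df.groupby(["sex", "event"]):
            grp = grp.sort_values("age")
            ages = grp["age"].to_numpy()
            if ages[0] != AGE_MIN or ages[-1] != AGE_MAX or len(ages) != AGE_MAX - AGE_MIN + 1:
                raise ValueError(f"incomplete age grid for ({sex}, {event})")
            rates[(sex, event)] = grp["rate"].to_numpy(dtype=float)
        return cls(rates)


def generate_baseline_rates(
    seed: int = 0,
    config: Mapping[str, GompertzConfig] | None = None,
    jitter_sd: float = 0.0,
) -> IncidenceTable:
    """Build the synthetic baseline :class:`IncidenceTable`.

    ``rate(sex, age, event) = a * exp(b * (age - 40)) * sex_ratio``, with
    optional log-normal jitter of standard deviation ``jitter_sd`` on the
    log scale (seeded, so deterministic given ``(seed, config)``). With
    ``jitter_sd=0`` the output is seed-independent.
    """
    config = dict(DEFAULT_CONFIG if config is None else config)
    missing = set(EVENTS) - set(config)
    if missing:
        raise ValueError(f"config missing events: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    ages = np.arange(AGE_MIN, AGE_MAX + 1, dtype=float)
    rates: dict = {}
    for event in EVENTS:  # fixed order keeps jitter reproducible
        g = config[event]
        base = g.a * np.exp(g.b * (ages - 40.0))
        for sex in SEXES:
            arr = base * (1.0 if sex == "male" else g.female_ratio)
            if jitter_sd > 0:
                arr = arr * np.exp(rng.normal(0.0, jitter_sd, size=arr.shape))
            rates[(sex, event)] = arr
    table = IncidenceTable(rates)
    table.validate()
    return table


def generate_calibration_targets(
    params,
    distortion: float = 1.0,
    start_age: int = 40,
) -> dict[tuple[str, int], float]:
    """CVD-specific mortality targets per (sex, decade band).

    Runs the untreated cohort model on baseline rates whose CVD components
    are scaled by ``distortion`` and records the achieved CVD mortality per
    person-year by sex and decade of age. Because the targets come from a
    run with known scaling, the calibration stage has exact ground truth:
    recovering per-band factors equal to ``distortion``.
    """
    if distortion <= 0:
        raise ValueError("distortion must be positive")
    from .calibration import achieved_cvd_mortality

    distorted = params.replace(
        baseline_rates=params.baseline_rates.uniformly_scaled(distortion)
    )
    return achieved_cvd_mortality(distorted, start_age=start_age)
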
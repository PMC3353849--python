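"""Model inputs: transition probabilities, relative risks, costs, distributions.

The model is parameterised by four tables plus baseline incidence rates:

* first-year secondary-event probabilities conditional on an acute event
  (case fatality, early reinfarction, stroke after infarction, ...);
* relative risks of new events in later years for each chronic health
  state, expressed against healthy (disease-free) subjects;
* head-to-head treatment relative risks per outcome, with an
  anchor comparison of calcium channel blockers against placebo;
* one-time event costs and per-year state/drug/monitoring costs in 2011
  euro (converted from Norwegian kroner at NOK 8.01 per euro).

Each uncertain quantity carries a :class:`DistributionSpec` for probabilistic
sensitivity analysis: beta for probabilities, log-normal for relative risks,
gamma for costs, ``fixed`` where no uncertainty interval is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "HealthState",
    "EventType",
    "Sex",
    "FirstYearTransition",
    "LaterYearRelativeRisk",
    "TreatmentEffect",
    "CostItem",
    "DistributionSpec",
    "ScenarioFlags",
    "ParameterSet",
    "distribution_from_estimate",
    "load_parameter_set",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class HealthState(str, Enum):
    """The nine health states of the cohort model."""

    DISEASE_FREE = "disease_free"
    POST_AMI = "post_ami"
    POST_ANGINA = "post_angina"
    POST_STROKE_NO_SEQUELAE = "post_stroke_no_sequelae"
    MODERATE_STROKE_SEQUELAE = "moderate_stroke_sequelae"
    SEVERE_STROKE_SEQUELAE = "severe_stroke_sequelae"
    HEART_FAILURE = "heart_failure"
    DEAD_CVD = "dead_cvd"
    DEAD_OTHER = "dead_other"

    @property
    def is_absorbing(self) -> bool:
        return self in (HealthState.DEAD_CVD, HealthState.DEAD_OTHER)


class EventType(str, Enum):
    AMI_STEMI = "ami_stemi"
    AMI_NONSTEMI = "ami_nonstemi"
    REINFARCTION = "reinfarction"
    STROKE = "stroke"
    ANGINA = "angina"
    HEART_FAILURE_EVENT = "heart_failure_event"
    HF_WORSENING = "hf_worsening"
    CVD_DEATH = "cvd_death"
    OTHER_DEATH = "other_death"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


# labels allowed in the delimited tables
_FIRST_YEAR_PRIMARY = {
    "angina", "ami", "stemi", "nonstemi", "reinfarction",
    "secondary_heart_failure", "primary_heart_failure", "stroke",
}
_FIRST_YEAR_SECONDARY = {
    "cvd_death", "death", "ami", "stroke", "angina", "heart_failure",
    "reinfarction", "transient", "moderate_sequelae", "severe_sequelae",
}
_LATER_EVENTS = {"ami", "angina", "death", "stroke", "heart_failure", "hf_worsening"}
_OUTCOMES = ("total_mortality", "ami", "stroke", "heart_failure", "angina")
_COMPARISONS = {
    "ace_vs_ccb", "diuretic_vs_ace", "ccb_vs_placebo",
    "arb_vs_ccb", "beta_blocker_vs_ccb",
}
_COST_KINDS = {"one_time_event", "per_year_state", "per_year_drug", "per_year_gp_visits"}


@dataclass(frozen=True)
class DistributionSpec:
    """Parametric uncertainty for a single model input.

    ``fixed`` carries the point value only; the other families carry the
    parameters in the usual convention (beta: alpha/beta; gamma:
    shape/scale; lognormal: mu/sigma of log).
    """

    family: str
    params: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "lognormal", "fixed"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family in ("beta", "gamma") and any(p <= 0 for p in self.params):
            raise ValueError(f"non-positive parameter in {self}")
        if self.family == "lognormal" and self.params[1] <= 0:
            raise ValueError("lognormal sigma must be positive")

    def mean(self) -> float:
        if self.family == "beta":
            a, b = self.params
            return a / (a + b)
        if self.family == "gamma":
            shape, scale = self.params
            return shape * scale
        if self.family == "lognormal":
            mu, sigma = self.params
            return math.exp(mu + sigma**2 / 2)
        raise ValueError("fixed spec has no analytic mean")

    def median(self) -> float:
        if self.family == "lognormal":
            return math.exp(self.params[0])
        raise NotImplementedError

    def var(self) -> float:
        if self.family == "beta":
            a, b = self.params
            return a * b / ((a + b) ** 2 * (a + b + 1))
        if self.family == "gamma":
            shape, scale = self.params
            return shape * scale**2
        if self.family == "lognormal":
            mu, sigma = self.params
            return (math.exp(sigma**2) - 1) * math.exp(2 * mu + sigma**2)
        raise ValueError("fixed spec has no variance")

    def sample(self, rng, point: float) -> float:
        """Draw one value; ``fixed`` returns the point value unchanged."""
        if self.family == "fixed":
            return point
        if self.family == "beta":
            return float(rng.beta(*self.params))
        if self.family == "gamma":
            shape, scale = self.params
            return float(rng.gamma(shape) * scale)
        mu, sigma = self.params
        return float(rng.lognormal(mu, sigma))


def distribution_from_estimate(
    mean: float, ci_low: float, ci_high: float, family: str
) -> DistributionSpec:
    """Fit a distribution to a point estimate with a 95% interval.

    The interval is treated as a symmetric normal 95% CI, so
    ``SE = (ci_high - ci_low) / (2 * 1.96)``, and moments are matched:

    * beta — method of moments on (mean, SE); the fitted mean equals the
      input mean;
    * gamma — ``shape = (mean/SE)^2``, ``scale = SE^2/mean``;
    * lognormal — ``mu = ln(mean)`` (median equals the point estimate),
      ``sigma = (ln ci_high - ln ci_low) / (2 * 1.96)``.

    A zero-width interval degrades to ``fixed``.
    """
    if not (ci_low <= mean <= ci_high):
        raise ValueError(f"estimate {mean} outside its interval [{ci_low}, {ci_high}]")
    if ci_high == ci_low:
        return DistributionSpec("fixed")
    se = (ci_high - ci_low) / (2 * Z95)
    if family == "beta":
        if not 0.0 < mean < 1.0:
            raise ValueError(f"beta requires mean in (0,1), got {mean}")
        nu = mean * (1 - mean) / se**2 - 1
        if nu <= 0:
            raise ValueError(f"interval too wide for beta at mean {mean}")
        return DistributionSpec("beta", (mean * nu, (1 - mean) * nu))
    if family == "gamma":
        if mean <= 0:
            raise ValueError("gamma requires positive mean")
        return DistributionSpec("gamma", ((mean / se) ** 2, se**2 / mean))
    if family == "lognormal":
        if min(mean, ci_low, ci_high) <= 0:
            raise ValueError("lognormal requires positive support")
        sigma = (math.log(ci_high) - math.log(ci_low)) / (2 * Z95)
        return DistributionSpec("lognormal", (math.log(mean), sigma))
    raise ValueError(f"unknown family {family!r}")


def _spec_for(value, ci_low, ci_high, family) -> DistributionSpec:
    if pd.isna(ci_low) or pd.isna(ci_high) or ci_low == ci_high:
        return DistributionSpec("fixed")
    return distribution_from_estimate(float(value), float(ci_low), float(ci_high), family)


@dataclass(frozen=True)
class FirstYearTransition:
    """One row of the first-year secondary-event table."""

    primary_event: str
    secondary_event: str
    probability: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    period: str
    sex: str = "both"
    age_low: Optional[int] = None
    age_high: Optional[int] = None
    provenance: str = ""
    spec: DistributionSpec = field(default=DistributionSpec("fixed"))

    def validate(self) -> None:
        if self.primary_event not in _FIRST_YEAR_PRIMARY:
            raise ValueError(
                f"unknown primary event {self.primary_event!r}; "
                f"allowed: {sorted(_FIRST_YEAR_PRIMARY)}"
            )
        if self.secondary_event not in _FIRST_YEAR_SECONDARY:
            raise ValueError(
                f"unknown secondary event {self.secondary_event!r}; "
                f"allowed: {sorted(_FIRST_YEAR_SECONDARY)}"
            )
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(
                f"probability {self.probability} out of [0,1] for "
                f"{self.primary_event}->{self.secondary_event}"
            )
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low <= self.probability <= self.ci_high:
                raise ValueError(
                    f"CI does not bracket value for {self.primary_event}->{self.secondary_event}"
                )


@dataclass(frozen=True)
class LaterYearRelativeRisk:
    """Relative risk of a new event vs healthy subjects, beyond the first year."""

    health_state: str
    event: str
    rr: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    sex: str = "both"
    age_low: Optional[int] = None
    age_high: Optional[int] = None
    year_band: Optional[str] = None  # second / third / later, or None for all
    provenance: str = ""
    spec: DistributionSpec = field(default=DistributionSpec("fixed"))

    def validate(self) -> None:
        HealthState(self.health_state)
        if self.event not in _LATER_EVENTS:
            raise ValueError(
                f"unknown event {self.event!r}; allowed: {sorted(_LATER_EVENTS)}"
            )
        if self.rr <= 0:
            raise ValueError(f"rr must be positive for {self.health_state}/{self.event}")
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low <= self.rr <= self.ci_high:
                raise ValueError(f"CI does not bracket rr for {self.health_state}/{self.event}")


@dataclass(frozen=True)
class TreatmentEffect:
    """Head-to-head (or vs-placebo) relative risk for one outcome."""

    comparison: str
    outcome: str
    rr: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    population_variant: str = "all"
    provenance: str = ""
    spec: DistributionSpec = field(default=DistributionSpec("fixed"))

    def validate(self) -> None:
        if self.comparison not in _COMPARISONS:
            raise ValueError(
                f"unknown comparison {self.comparison!r}; allowed: {sorted(_COMPARISONS)}"
            )
        if self.outcome not in _OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}; allowed: {_OUTCOMES}")
        if self.rr <= 0:
            raise ValueError("rr must be positive")


@dataclass(frozen=True)
class CostItem:
    label: str
    kind: str
    value: float
    spec: DistributionSpec = field(default=DistributionSpec("fixed"))

    def validate(self) -> None:
        if self.kind not in _COST_KINDS:
            raise ValueError(f"unknown cost kind {self.kind!r}")
        if self.value < 0:
            raise ValueError(f"negative cost for {self.label}")


@dataclass(frozen=True)
class ScenarioFlags:
    include_hf_angina_efficacy: bool = False
    population_variant: str = "african_american_excluded"


@dataclass
class ParameterSet:
    """Complete input bundle for one model run."""

    first_year: tuple[FirstYearTransition, ...]
    later_year: tuple[LaterYearRelativeRisk, ...]
    effects: tuple[TreatmentEffect, ...]
    costs: tuple[CostItem, ...]
    baseline_rates: "object" = None  # IncidenceTable; set by synthetic_data or loader
    discount_rate: float = 0.04
    threshold: float = 62_000.0
    stemi_share: float = 0.5
    scenario_flags: ScenarioFlags = field(default_factory=ScenarioFlags)

    # --- lookups -----------------------------------------------------------

    def first_year_prob(
        self,
        primary: str,
        secondary: str,
        sex: Optional[str] = None,
        age: Optional[int] = None,
        period: Optional[str] = None,
    ) -> float:
        """Resolve one first-year probability, honouring sex and age bands.

        When both six-month and in-hospital stroke rows exist for the same
        acute event, the larger six-month figure is used alone (the shorter
        window is subsumed; using both would double count).
        """
        rows = [
            r
            for r in self.first_year
            if r.primary_event == primary
            and r.secondary_event == secondary
            and r.sex in ("both", sex)
            and (r.age_low is None or (age is not None and r.age_low <= age <= r.age_high))
            and (period is None or r.period == period)
        ]
        if not rows:
            raise KeyError(f"no first-year row for {primary}->{secondary} (sex={sex}, age={age})")
        if len(rows) > 1:
            rows = sorted(rows, key=lambda r: r.probability, reverse=True)[:1]
        return rows[0].probability

    def later_rr(
        self,
        health_state: str,
        event: str,
        sex: Optional[str] = None,
        age: Optional[int] = None,
        year_band: Optional[str] = None,
    ) -> float:
        rows = [
            r
            for r in self.later_year
            if r.health_state == health_state
            and r.event == event
            and r.sex in ("both", sex)
            and (r.age_low is None or (age is not None and r.age_low <= age <= r.age_high))
            and (r.year_band is None or r.year_band == year_band)
        ]
        if not rows:
            raise KeyError(
                f"no later-year row for {health_state}/{event} "
                f"(sex={sex}, age={age}, year_band={year_band})"
            )
        # prefer the most specific row (sex- or band-specific over generic)
        rows.sort(key=lambda r: (r.sex != "both", r.year_band is not None), reverse=True)
        return rows[0].rr

    def later_rows(self, health_state: str) -> list[LaterYearRelativeRisk]:
        return [r for r in self.later_year if r.health_state == health_state]

    def effect(self, comparison: str, outcome: str, variant: Optional[str] = None) -> TreatmentEffect:
        variant = variant or self.scenario_flags.population_variant
        rows = [
            r
            for r in self.effects
            if r.comparison == comparison
            and r.outcome == outcome
            and r.population_variant in ("all", variant)
        ]
        if not rows:
            raise KeyError(f"no treatment effect for {comparison}/{outcome} ({variant})")
        rows.sort(key=lambda r: r.population_variant != "all")
        return rows[-1] if any(r.population_variant == variant for r in rows) else rows[0]

    def cost(self, label: str) -> float:
        for c in self.costs:
            if c.label == label:
                return c.value
        raise KeyError(f"no cost item {label!r}")

    # --- validation / serialization ---------------------------------------

    def validate(self) -> None:
        for coll in (self.first_year, self.later_year, self.effects, self.costs):
            for row in coll:
                row.validate()
        for comparison in ("ace_vs_ccb", "diuretic_vs_ace"):
            for variant in ("all_included", "african_american_excluded"):
                for outcome in _OUTCOMES:
                    self.effect(comparison, outcome, variant)
        for outcome in _OUTCOMES:
            self.effect("ccb_vs_placebo", outcome)
        if not 0 <= self.discount_rate < 1:
            raise ValueError("discount rate must be in [0,1)")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not 0 <= self.stemi_share <= 1:
            raise ValueError("stemi_share must be in [0,1]")

    def replace(self, **kwargs) -> "ParameterSet":
        new = ParameterSet(**{**self.__dict__, **kwargs})
        return new

    def to_frames(self) -> dict[str, pd.DataFrame]:
        def frame(rows: Iterable, cols: Sequence[str]) -> pd.DataFrame:
            return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in rows])

        fy = frame(
            self.first_year,
            ["primary_event", "secondary_event", "sex", "age_low", "age_high",
             "ci_low", "ci_high", "period", "provenance"],
        )
        fy.insert(5, "value", [r.probability for r in self.first_year])
        return {
            "first_year": fy,
            "later_year": frame(
                self.later_year,
                ["health_state", "event", "sex", "age_low", "age_high",
                 "year_band", "rr", "ci_low", "ci_high", "provenance"],
            ),
            "effects": frame(
                self.effects,
                ["comparison", "outcome", "population_variant", "rr",
                 "ci_low", "ci_high", "provenance"],
            ),
            "costs": frame(self.costs, ["label", "kind", "value"]),
        }

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        frames = self.to_frames()
        frames["first_year"].to_csv(directory / "first_year.csv", index=False)
        frames["later_year"].to_csv(directory / "later_year.csv", index=False)
        eff = frames["effects"]
        eff[eff.provenance != "synthetic"].to_csv(
            directory / "treatment_effects.csv", index=False
        )
        eff[eff.provenance == "synthetic"].to_csv(
            directory / "treatment_effects_synthetic.csv", index=False
        )
        frames["costs"].to_csv(directory / "costs.csv", index=False)
        if self.baseline_rates is not None:
            self.baseline_rates.to_frame().to_csv(
                directory / "baseline_rates.csv", index=False
            )


def _opt_int(v) -> Optional[int]:
    return None if pd.isna(v) else int(v)


def _opt_float(v) -> Optional[float]:
    return None if pd.isna(v) else float(v)


def _read(path: Path, name: str) -> pd.DataFrame:
    f = path / name
    if not f.exists():
        raise FileNotFoundError(f"mandatory table {name} missing from {path}")
    return pd.read_csv(f, float_precision="round_trip")


def _default_dir() -> Path:
    return Path(resources.files("cardiocea") / "data")


def load_parameter_set(
    paths: Optional[str | Path] = None,
    overrides: Optional[Mapping[str, object]] = None,
    baseline_rates: "object" = None,
) -> ParameterSet:
    """Load and validate a :class:`ParameterSet` from delimited tables.

    ``paths`` is a directory holding ``first_year.csv``, ``later_year.csv``,
    ``treatment_effects.csv``, ``costs.csv`` and optionally
    ``treatment_effects_synthetic.csv`` and ``baseline_rates.csv``; the
    packaged defaults are used when omitted. ``overrides`` patches scalar
    run settings (``discount_rate``, ``threshold``, ``stemi_share``,
    scenario flags, ``cost_uncertainty_cv``) after loading.
    """
    directory = Path(paths) if paths is not None else _default_dir()
    overrides = dict(overrides or {})

    fy_df = _read(directory, "first_year.csv")
    first_year = tuple(
        FirstYearTransition(
            primary_event=r.primary_event,
            secondary_event=r.secondary_event,
            probability=float(r.value),
            ci_low=_opt_float(r.ci_low),
            ci_high=_opt_float(r.ci_high),
            period=r.period,
            sex=r.sex,
            age_low=_opt_int(r.age_low),
            age_high=_opt_int(r.age_high),
            provenance=getattr(r, "provenance", ""),
            spec=_spec_for(r.value, r.ci_low, r.ci_high, "beta"),
        )
        for r in fy_df.itertuples()
    )

    ly_df = _read(directory, "later_year.csv")
    later_year = tuple(
        LaterYearRelativeRisk(
            health_state=r.health_state,
            event=r.event,
            rr=float(r.rr),
            ci_low=_opt_float(r.ci_low),
            ci_high=_opt_float(r.ci_high),
            sex=r.sex,
            age_low=_opt_int(r.age_low),
            age_high=_opt_int(r.age_high),
            year_band=None if pd.isna(r.year_band) else str(r.year_band),
            provenance=getattr(r, "provenance", ""),
            spec=_spec_for(r.rr, r.ci_low, r.ci_high, "lognormal"),
        )
        for r in ly_df.itertuples()
    )

    eff_df = _read(directory, "treatment_effects.csv")
    synth_path = directory / "treatment_effects_synthetic.csv"
    if synth_path.exists():
        eff_df = pd.concat([eff_df, pd.read_csv(synth_path)], ignore_index=True)
    effects = tuple(
        TreatmentEffect(
            comparison=r.comparison,
            outcome=r.outcome,
            rr=float(r.rr),
            ci_low=_opt_float(r.ci_low),
            ci_high=_opt_float(r.ci_high),
            population_variant=r.population_variant,
            provenance=getattr(r, "provenance", ""),
            spec=_spec_for(r.rr, r.ci_low, r.ci_high, "lognormal"),
        )
        for r in eff_df.itertuples()
    )

    cost_df = _read(directory, "costs.csv")
    cv = overrides.pop("cost_uncertainty_cv", None)
    costs = tuple(
        CostItem(
            label=r.label,
            kind=r.kind,
            value=float(r.value),
            spec=(
                DistributionSpec("fixed")
                if cv is None or r.value == 0
                else DistributionSpec("gamma", (1.0 / cv**2, cv**2 * float(r.value)))
            ),
        )
        for r in cost_df.itertuples()
    )

    if baseline_rates is None and (directory / "baseline_rates.csv").exists():
        from .synthetic_data import IncidenceTable

        baseline_rates = IncidenceTable.from_frame(
            pd.read_csv(directory / "baseline_rates.csv", float_precision="round_trip")
        )

    flag_fields = {}
    for key in ("include_hf_angina_efficacy", "population_variant"):
        if key in overrides:
            flag_fields[key] = overrides.pop(key)
    flags = ScenarioFlags(**flag_fields)

    ps = ParameterSet(
        first_year=first_year,
        later_year=later_year,
        effects=effects,
        costs=costs,
        baseline_rates=baseline_rates,
        scenario_flags=flags,
    )
    for key, value in overrides.items():
        if not hasattr(ps, key):
            raise KeyError(f"unknown override {key!r}")
        setattr(ps, key, value)
    ps.validate()
    return ps
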
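"""Annual-cycle cohort engine for the cardiovascular disease model.

A cohort enters disease-free at a start age and is propagated through
annual cycles until everyone is dead or reaches 100 years. Primary events
strike disease-free individuals at baseline population rates (times the
treatment relative risks); the cycle in which an acute event occurs is its
"first year", during which the event-conditional secondary risks apply
(case fatality, early reinfarction, stroke after infarction, secondary
heart failure). Survivors settle into a chronic health state; from the
second year onward their event risks are the baseline age-specific rates
multiplied by state-specific relative risks versus healthy subjects.

Memory follows the worst-state rule: a patient keeps the risks and costs of
the most severe state reached, with severity ordered

    severe stroke sequelae > moderate sequelae > heart failure >
    asymptomatic post-event states (tie broken by the most recent event) >
    disease-free.

Heart failure carries a three-level tunnel clock because its mortality is
specific to the second, third and later years after onset. Secondary heart
failure is transient with probability 0.5 (it resolves within 6-12 months),
in which case the patient reverts to the prior worst state.

Life years and per-year costs are credited to the cohort alive at cycle
start, without half-cycle correction; one-time event costs are discounted
at the cycle in which the event occurs. At the age-100 boundary any
remaining survivors are moved to death from other causes.

The expanded state space (health state x heart-failure tunnel year) is
small, so the cohort is propagated exactly; :func:`run_microsim` walks
individuals through the identical per-(age, state) outcome distributions
and serves as an independent stochastic cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .parameters import HealthState, ParameterSet
from .treatment import Strategy, annual_treatment_cost, apply_treatment, strategy_effective_rr

__all__ = [
    "PatientProfile",
    "CohortTrace",
    "MicrosimResult",
    "EngineContext",
    "severity_order",
    "rate_to_prob",
    "normalize_competing",
    "cycle_event_probabilities",
    "run_cohort",
    "run_microsim",
    "STATE_NAMES",
]

# expanded state indices (heart failure split by years since onset)
DISEASE_FREE = 0
POST_AMI = 1
POST_ANGINA = 2
POST_STROKE = 3
MOD_SEQ = 4
SEV_SEQ = 5
HF_Y1 = 6
HF_Y2 = 7
HF_Y3P = 8
DEAD_CVD = 9
DEAD_OTHER = 10

N_STATES = 11
ALIVE = tuple(range(9))

STATE_NAMES = (
    "disease_free", "post_ami", "post_angina", "post_stroke_no_sequelae",
    "moderate_stroke_sequelae", "severe_stroke_sequelae",
    "heart_failure_y1", "heart_failure_y2", "heart_failure_y3plus",
    "dead_cvd", "dead_other",
)

_HS_OF = (
    "disease_free", "post_ami", "post_angina", "post_stroke_no_sequelae",
    "moderate_stroke_sequelae", "severe_stroke_sequelae",
    "heart_failure", "heart_failure", "heart_failure",
    "dead_cvd", "dead_other",
)

_CHRONIC_IDX = {
    "disease_free": DISEASE_FREE,
    "post_ami": POST_AMI,
    "post_angina": POST_ANGINA,
    "post_stroke_no_sequelae": POST_STROKE,
    "moderate_stroke_sequelae": MOD_SEQ,
    "severe_stroke_sequelae": SEV_SEQ,
    "heart_failure": HF_Y1,
}

_SEVERITY = {
    "disease_free": 0,
    "post_ami": 1,
    "post_angina": 1,
    "post_stroke_no_sequelae": 1,
    "heart_failure": 2,
    "moderate_stroke_sequelae": 3,
    "severe_stroke_sequelae": 4,
}

_HF_YEAR_BAND = {HF_Y1: "second", HF_Y2: "third", HF_Y3P: "later"}

_MAX_CHAIN_DEPTH = 2  # nonfatal secondary chains are truncated beyond this

_renormalizations = 0


def renormalization_count() -> int:
    """Number of times a cycle's event probabilities had to be rescaled."""
    return _renormalizations


def severity_order(state: str | HealthState) -> int:
    """Rank of a living health state under the worst-state rule."""
    name = state.value if isinstance(state, HealthState) else str(state)
    try:
        return _SEVERITY[name]
    except KeyError:
        raise ValueError(f"{name!r} has no severity rank (dead or unknown)") from None


def _worst(current: str, candidate: str) -> str:
    """Worst-state update; equal severity goes to the most recent event."""
    return candidate if _SEVERITY[candidate] >= _SEVERITY[current] else current


def rate_to_prob(rate: float, t: float = 1.0) -> float:
    """Convert a constant hazard to a probability over ``t`` years."""
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if t <= 0:
        raise ValueError("t must be positive")
    return 1.0 - math.exp(-rate * t)


def normalize_competing(events: Mapping[str, float]) -> tuple[dict[str, float], float]:
    """Resolve competing risks within one cycle.

    Returns the (possibly rescaled) event map and the residual stay-put
    probability. Probabilities summing above one are rescaled to sum to one
    and the module-level renormalization counter is incremented.
    """
    global _renormalizations
    total = float(sum(events.values()))
    if total <= 1.0:
        return dict(events), 1.0 - total
    _renormalizations += 1
    return {k: v / total for k, v in events.items()}, 0.0


@dataclass(frozen=True)
class PatientProfile:
    sex: str
    start_age: int

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if not 30 <= self.start_age < 100:
            raise ValueError("start_age must be in [30, 100)")


Branch = tuple[int, float, float]  # destination, probability, one-time cost


class EngineContext:
    """Caches per-(age, state) outcome branch distributions for one
    parameter set and sex; shared between the cohort engine, the
    microsimulation and across strategies (treatment only alters the
    disease-free branches)."""

    def __init__(self, params: ParameterSet, sex: str):
        self.params = params
        self.sex = sex
        self._cache: dict = {}
        self._cardiac = params.cost("cardiac_death_hospital")

    # -- first-year resolution helpers -------------------------------------

    def _fy(self, primary: str, secondary: str, age: Optional[int] = None) -> float:
        return self.params.first_year_prob(primary, secondary, sex=self.sex, age=age)

    def resolve_event(
        self, event: str, w: str, age: int, depth: int = 0, current_idx: Optional[int] = None
    ) -> list[Branch]:
        """Distribution over end-of-cycle states (with one-time costs) given
        that ``event`` strikes a patient whose worst state is ``w``."""
        p = self.params
        if event == "other_death":
            return [(DEAD_OTHER, 1.0, 0.0)]
        if event == "cvd_death":
            return [(DEAD_CVD, 1.0, self._cardiac)]
        if event == "hf_worsening":
            return [(_advance(current_idx), 1.0, p.cost("hf_worsening_event"))]
        if event == "ami":
            share = p.stemi_share
            out: list[Branch] = []
            for subtype, wgt in (("stemi", share), ("nonstemi", 1.0 - share)):
                if wgt > 0:
                    out.extend(
                        (d, wgt * pr, c) for d, pr, c in self._acute_mi(subtype, w, age, depth)
                    )
            return out
        if event == "stroke":
            return self._stroke(w, depth)
        if event == "angina":
            return self._angina(w, age, depth)
        if event == "heart_failure_event":
            if w == "disease_free":
                return self._primary_hf()
            return self._secondary_hf(w, depth)
        raise ValueError(f"cannot resolve event {event!r}")

    def _acute_mi(self, subtype: str, w: str, age: int, depth: int) -> list[Branch]:
        c0 = self.params.cost(f"{subtype}_event")
        w2 = _worst(w, "post_ami")
        sub = {"death": self._fy("ami", "death", age=age)}
        if depth < _MAX_CHAIN_DEPTH:
            sub["heart_failure"] = self._fy(subtype, "heart_failure")
            sub["reinfarction"] = self._fy(subtype, "reinfarction")
            sub["stroke"] = self._fy(subtype, "stroke")
            sub["angina"] = self._fy(subtype, "angina")
        probs, residual = normalize_competing(sub)
        out: list[Branch] = [(_CHRONIC_IDX[w2], residual, c0)]
        for ev, pr in probs.items():
            if pr == 0:
                continue
            if ev == "death":
                out.append((DEAD_CVD, pr, c0 + self._cardiac))
            elif ev == "heart_failure":
                out.extend(_chain(pr, c0, self._secondary_hf(w2, depth + 1)))
            elif ev == "reinfarction":
                out.extend(_chain(pr, c0, self._reinfarction(w2, age, depth + 1)))
            elif ev == "stroke":
                out.extend(_chain(pr, c0, self._stroke(w2, depth + 1)))
            else:  # angina
                out.extend(_chain(pr, c0, self._angina(w2, age, depth + 1)))
        return out

    def _stroke(self, w: str, depth: int) -> list[Branch]:
        c0 = self.params.cost("stroke_event")
        d = self._fy("stroke", "death")
        mod = self._fy("stroke", "moderate_sequelae")
        sev = self._fy("stroke", "severe_sequelae")
        probs, residual = normalize_competing(
            {"death": d, "moderate": mod, "severe": sev}
        )
        return [
            (DEAD_CVD, probs["death"], c0 + self._cardiac),
            (_CHRONIC_IDX[_worst(w, "moderate_stroke_sequelae")], probs["moderate"], c0),
            (_CHRONIC_IDX[_worst(w, "severe_stroke_sequelae")], probs["severe"], c0),
            (_CHRONIC_IDX[_worst(w, "post_stroke_no_sequelae")], residual, c0),
        ]

    def _angina(self, w: str, age: int, depth: int) -> list[Branch]:
        c0 = self.params.cost("angina_event")
        w2 = _worst(w, "post_angina")
        sub = {"cvd_death": self._fy("angina", "cvd_death")}
        if depth < _MAX_CHAIN_DEPTH:
            sub["ami"] = self._fy("angina", "ami")
            sub["stroke"] = self._fy("angina", "stroke")
            sub["heart_failure"] = self._fy("angina", "heart_failure")
        probs, residual = normalize_competing(sub)
        out: list[Branch] = [(_CHRONIC_IDX[w2], residual, c0)]
        for ev, pr in probs.items():
            if ev == "cvd_death":
                out.append((DEAD_CVD, pr, c0 + self._cardiac))
            elif ev == "ami":
                out.extend(_chain(pr, c0, self.resolve_event("ami", w2, age, depth + 1)))
            elif ev == "stroke":
                out.extend(_chain(pr, c0, self._stroke(w2, depth + 1)))
            else:
                out.extend(_chain(pr, c0, self._secondary_hf(w2, depth + 1)))
        return out

    def _primary_hf(self) -> list[Branch]:
        c0 = self.params.cost("heart_failure_event")
        d = self._fy("primary_heart_failure", "death")
        return [(DEAD_CVD, d, c0 + self._cardiac), (HF_Y1, 1.0 - d, c0)]

    def _secondary_hf(self, w: str, depth: int) -> list[Branch]:
        c0 = self.params.cost("heart_failure_event")
        d = self._fy("secondary_heart_failure", "death")
        transient = self._fy("secondary_heart_failure", "transient")
        out: list[Branch] = [(DEAD_CVD, d, c0 + self._cardiac)]
        surv = 1.0 - d
        if _SEVERITY["heart_failure"] > _SEVERITY[w]:
            out.append((_CHRONIC_IDX[w], surv * transient, c0))
            out.append((HF_Y1, surv * (1.0 - transient), c0))
        else:
            # the prior state is at least as severe; HF adds cost and
            # mortality risk but does not displace it
            out.append((_CHRONIC_IDX[w], surv, c0))
        return out

    def _reinfarction(self, w: str, age: int, depth: int) -> list[Branch]:
        c0 = self.params.cost("reinfarction_event")
        w2 = _worst(w, "post_ami")
        share = self.params.stemi_share
        sub = {"death": self._fy("reinfarction", "death")}
        if depth < _MAX_CHAIN_DEPTH:
            # stroke/angina/heart failure after reinfarction mirror the
            # STEMI / non-STEMI first-year risks
            for ev in ("heart_failure", "stroke", "angina"):
                sub[ev] = share * self._fy("stemi", ev) + (1 - share) * self._fy("nonstemi", ev)
        probs, residual = normalize_competing(sub)
        out: list[Branch] = [(_CHRONIC_IDX[w2], residual, c0)]
        for ev, pr in probs.items():
            if ev == "death":
                out.append((DEAD_CVD, pr, c0 + self._cardiac))
            elif ev == "heart_failure":
                out.extend(_chain(pr, c0, self._secondary_hf(w2, depth + 1)))
            elif ev == "stroke":
                out.extend(_chain(pr, c0, self._stroke(w2, depth + 1)))
            else:
                out.extend(_chain(pr, c0, self._angina(w2, age, depth + 1)))
        return out

    # -- per-cycle transition ----------------------------------------------

    def transition(
        self, age: int, s_idx: int, eff: Optional[Mapping[str, float]] = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Arrays (destinations, probabilities, costs, cumulative probs) for
        one cycle from expanded state ``s_idx`` at ``age``."""
        eff_key = None if (eff is None or s_idx != DISEASE_FREE) else tuple(sorted(eff.items()))
        key = (age, s_idx, eff_key)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        evmap = cycle_event_probabilities(self.params, s_idx, self.sex, age, eff)
        probs, residual = normalize_competing(evmap)
        branches: list[Branch] = []
        if residual > 0:
            branches.append((_advance(s_idx), residual, 0.0))
        for ev, pr in probs.items():
            if pr == 0:
                continue
            branches.extend(
                (d, pr * bp, c)
                for d, bp, c in self.resolve_event(ev, _HS_OF[s_idx], age, 0, s_idx)
                if bp > 0
            )
        merged: dict[tuple[int, float], float] = {}
        for d, pr, c in branches:
            merged[(d, round(c, 6))] = merged.get((d, round(c, 6)), 0.0) + pr
        dests = np.array([k[0] for k in merged], dtype=np.int64)
        ps = np.array(list(merged.values()), dtype=float)
        costs = np.array([k[1] for k in merged], dtype=float)
        cum = np.cumsum(ps)
        cum[-1] = 1.0  # guard float drift for the sampler
        out = (dests, ps, costs, cum)
        self._cache[key] = out
        return out


def _advance(s_idx: int) -> int:
    if s_idx == HF_Y1:
        return HF_Y2
    if s_idx == HF_Y2:
        return HF_Y3P
    return s_idx


def _chain(p: float, extra_cost: float, branches: Sequence[Branch]) -> list[Branch]:
    return [(d, p * bp, extra_cost + c) for d, bp, c in branches if bp > 0]


def cycle_event_probabilities(
    params: ParameterSet,
    s_idx: int,
    sex: str,
    age: int,
    eff: Optional[Mapping[str, float]] = None,
) -> dict[str, float]:
    """Event probability map for one cycle in expanded state ``s_idx``.

    Disease-free: baseline primary-event probabilities with treatment
    relative risks applied. Chronic states: baseline probability times the
    state's later-year relative risk, capped at one. Death from other causes
    is always drawn from the baseline table and never treated.
    """
    hs = _HS_OF[s_idx]
    if hs in ("dead_cvd", "dead_other"):
        raise ValueError("no events from absorbing states")
    base = params.baseline_rates
    if base is None:
        raise ValueError("ParameterSet has no baseline incidence rates")
    out: dict[str, float] = {}
    if s_idx == DISEASE_FREE:
        for ev in ("ami", "stroke", "angina", "heart_failure_event", "cvd_death"):
            out[ev] = rate_to_prob(base.rate(sex, age, ev))
        if eff:
            out = apply_treatment(out, eff, params.scenario_flags)
    else:
        seen = set()
        for row in params.later_rows(hs):
            if row.event in seen:
                continue
            seen.add(row.event)
            band = _HF_YEAR_BAND.get(s_idx) if hs == "heart_failure" else None
            rr = params.later_rr(hs, row.event, sex=sex, age=age, year_band=band)
            if row.event == "death":
                ev_name, base_ev = "cvd_death", "cvd_death"
            elif row.event == "heart_failure":
                ev_name, base_ev = "heart_failure_event", "heart_failure_event"
            elif row.event == "hf_worsening":
                ev_name, base_ev = "hf_worsening", "heart_failure_event"
            else:
                ev_name, base_ev = row.event, row.event
            out[ev_name] = min(1.0, rate_to_prob(base.rate(sex, age, base_ev)) * rr)
    out["other_death"] = rate_to_prob(base.rate(sex, age, "other_death"))
    return out


@dataclass
class CohortTrace:
    """State occupancy and accumulated outcomes over the annual cycles."""

    ages: np.ndarray              # age at each cycle start
    occupancy: np.ndarray         # (n_cycles + 1, N_STATES); last row after age-100 boundary
    ly_undisc: np.ndarray
    ly_disc: np.ndarray
    cost_undisc: np.ndarray
    cost_disc: np.ndarray
    cvd_deaths: np.ndarray        # newly dead from CVD per cycle (cohort fraction)
    discount_rate: float

    @property
    def total_ly_disc(self) -> float:
        return float(self.ly_disc.sum())

    @property
    def total_ly_undisc(self) -> float:
        return float(self.ly_undisc.sum())

    @property
    def total_cost_disc(self) -> float:
        return float(self.cost_disc.sum())

    @property
    def total_cost_undisc(self) -> float:
        return float(self.cost_undisc.sum())

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.occupancy[:-1], columns=STATE_NAMES)
        df.insert(0, "age", self.ages)
        df["cycle_ly_undisc"] = self.ly_undisc
        df["cycle_ly_disc"] = self.ly_disc
        df["cycle_cost_undisc"] = self.cost_undisc
        df["cycle_cost_disc"] = self.cost_disc
        return df


def _state_cost_vector(params: ParameterSet) -> np.ndarray:
    v = np.zeros(N_STATES)
    v[POST_AMI] = params.cost("post_ami_year")
    v[POST_ANGINA] = params.cost("post_angina_year")
    v[POST_STROKE] = params.cost("post_stroke_year")
    v[MOD_SEQ] = params.cost("moderate_stroke_sequelae_year")
    v[SEV_SEQ] = params.cost("severe_stroke_sequelae_year")
    v[HF_Y1] = v[HF_Y2] = v[HF_Y3P] = params.cost("heart_failure_year")
    return v


def run_cohort(
    params: ParameterSet,
    profile: PatientProfile,
    strategy: Optional[Strategy] = None,
    ctx: Optional[EngineContext] = None,
    treat_while: str = "alive",
) -> CohortTrace:
    """Propagate the full cohort deterministically and return its trace.

    ``treat_while`` controls whether primary-prevention drug and monitoring
    costs continue for every survivor (``"alive"``, the default) or stop
    once the patient leaves the disease-free state (``"disease_free"``).
    """
    strategy = strategy or Strategy()
    if ctx is None:
        ctx = EngineContext(params, profile.sex)
    eff = strategy_effective_rr(strategy, params) if strategy.drugs else None
    rate = params.discount_rate
    state_cost = _state_cost_vector(params)

    ages = np.arange(profile.start_age, 100)
    n = len(ages)
    occupancy = np.zeros((n + 1, N_STATES))
    ly_u = np.zeros(n)
    ly_d = np.zeros(n)
    cost_u = np.zeros(n)
    cost_d = np.zeros(n)
    cvd_deaths = np.zeros(n)

    occ = np.zeros(N_STATES)
    occ[DISEASE_FREE] = 1.0
    for t, age in enumerate(ages):
        occupancy[t] = occ
        alive = float(occ[: DEAD_CVD].sum())
        df = (1.0 + rate) ** (-t)
        ly_u[t] = alive
        ly_d[t] = alive * df
        cycle_cost = float(occ @ state_cost)
        if strategy.drugs:
            treated = alive if treat_while == "alive" else float(occ[DISEASE_FREE])
            cycle_cost += treated * annual_treatment_cost(strategy, t + 1, params)
        new_occ = np.zeros(N_STATES)
        new_occ[DEAD_CVD] = occ[DEAD_CVD]
        new_occ[DEAD_OTHER] = occ[DEAD_OTHER]
        for s in ALIVE:
            mass = occ[s]
            if mass <= 0.0:
                continue
            dests, ps, costs, _ = ctx.transition(int(age), s, eff)
            np.add.at(new_occ, dests, mass * ps)
            cycle_cost += mass * float(ps @ costs)
        cvd_deaths[t] = new_occ[DEAD_CVD] - occ[DEAD_CVD]
        cost_u[t] = cycle_cost
        cost_d[t] = cycle_cost * df
        occ = new_occ
    # age-100 boundary: survivors are moved to death from other causes
    occ[DEAD_OTHER] += occ[: DEAD_CVD].sum()
    occ[: DEAD_CVD] = 0.0
    occupancy[n] = occ

    return CohortTrace(
        ages=ages,
        occupancy=occupancy,
        ly_undisc=ly_u,
        ly_disc=ly_d,
        cost_undisc=cost_u,
        cost_disc=cost_d,
        cvd_deaths=cvd_deaths,
        discount_rate=rate,
    )


@dataclass
class MicrosimResult:
    """Means and Monte-Carlo standard errors from the individual-level walk."""

    n: int
    seed: int
    ly_disc: float
    ly_disc_se: float
    cost_disc: float
    cost_disc_se: float
    ly_undisc: float
    cost_undisc: float


def run_microsim(
    params: ParameterSet,
    profile: PatientProfile,
    strategy: Optional[Strategy] = None,
    n: int = 10_000,
    seed: int = 0,
    ctx: Optional[EngineContext] = None,
    treat_while: str = "alive",
) -> MicrosimResult:
    """Individual-level Monte Carlo walk through the identical transition
    rules as :func:`run_cohort`; the independent oracle for the cohort
    engine."""
    if n < 1:
        raise ValueError("n must be >= 1")
    strategy = strategy or Strategy()
    if ctx is None:
        ctx = EngineContext(params, profile.sex)
    eff = strategy_effective_rr(strategy, params) if strategy.drugs else None
    rate = params.discount_rate
    state_cost = _state_cost_vector(params)
    rng = np.random.default_rng(seed)

    state = np.full(n, DISEASE_FREE, dtype=np.int64)
    ly_d = np.zeros(n)
    ly_u = np.zeros(n)
    cost_d = np.zeros(n)
    cost_u = np.zeros(n)

    for t, age in enumerate(range(profile.start_age, 100)):
        alive_mask = state < DEAD_CVD
        if not alive_mask.any():
            break
        df = (1.0 + rate) ** (-t)
        ly_d[alive_mask] += df
        ly_u[alive_mask] += 1.0
        treat = annual_treatment_cost(strategy, t + 1, params) if strategy.drugs else 0.0
        new_state = state.copy()
        for s in ALIVE:
            idx = np.nonzero(state == s)[0]
            if idx.size == 0:
                continue
            percyc = state_cost[s] + (
                treat if (treat_while == "alive" or s == DISEASE_FREE) else 0.0
            )
            cost_d[idx] += percyc * df
            cost_u[idx] += percyc
            dests, _, costs, cum = ctx.transition(int(age), s, eff)
            k = np.searchsorted(cum, rng.random(idx.size), side="right")
            new_state[idx] = dests[k]
            cost_d[idx] += costs[k] * df
            cost_u[idx] += costs[k]
        state = new_state
    state[state < DEAD_CVD] = DEAD_OTHER

    sq = math.sqrt(n)
    return MicrosimResult(
        n=n,
        seed=seed,
        ly_disc=float(ly_d.mean()),
        ly_disc_se=float(ly_d.std(ddof=1) / sq) if n > 1 else 0.0,
        cost_disc=float(cost_d.mean()),
        cost_disc_se=float(cost_d.std(ddof=1) / sq) if n > 1 else 0.0,
        ly_undisc=float(ly_u.mean()),
        cost_undisc=float(cost_u.mean()),
    )
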
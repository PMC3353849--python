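"""Treatment strategies: anchored relative risks and annual drug costs.

Head-to-head trial evidence compares drugs against calcium channel blockers
(CCB); only CCB has a placebo-controlled anchor. A drug's effect versus no
treatment is therefore built multiplicatively along the comparison chain:

    rr(drug vs placebo) = rr(CCB vs placebo) * rr(drug vs CCB)

with thiazides reaching CCB through ACE inhibitors
(``diuretic_vs_ace * ace_vs_ccb``). Combinations of two or three drugs are
assumed to interact multiplicatively, so the combined relative risk is the
product of the single-drug relative risks (a 0.9 and a 0.8 drug give
``0.72``, i.e. a 28% relative risk reduction).

Effects apply to *primary* events only; probabilities conditional on having
had an event (the first-year and later-year tables) are never modified. In
the base case heart-failure and angina primary events are not modified
either — those outcomes are softer trial endpoints — unless the scenario
flag ``include_hf_angina_efficacy`` is set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "DRUGS",
    "OUTCOMES",
    "Strategy",
    "rr_vs_no_treatment",
    "strategy_effective_rr",
    "combine_rrs",
    "apply_treatment",
    "annual_treatment_cost",
]

DRUGS = ("thiazide", "ace", "ccb", "arb", "beta_blocker")
OUTCOMES = ("total_mortality", "ami", "stroke", "heart_failure", "angina")

# comparison chain from each drug to the CCB-vs-placebo anchor
_CHAINS: dict[str, tuple[str, ...]] = {
    "ccb": (),
    "ace": ("ace_vs_ccb",),
    "thiazide": ("diuretic_vs_ace", "ace_vs_ccb"),
    "arb": ("arb_vs_ccb",),
    "beta_blocker": ("beta_blocker_vs_ccb",),
}

_DRUG_COST_LABEL = {
    "thiazide": "thiazide_year",
    "ace": "ace_year",
    "ccb": "ccb_year",
    "arb": "arb_year",
    "beta_blocker": "beta_blocker_year",
}


@dataclass(frozen=True)
class Strategy:
    """A set of 0-3 antihypertensive drugs; the empty set is no treatment."""

    drugs: tuple[str, ...] = ()
    label: Optional[str] = None

    def __post_init__(self) -> None:
        drugs = tuple(sorted(self.drugs))
        object.__setattr__(self, "drugs", drugs)
        unknown = set(drugs) - set(DRUGS)
        if unknown:
            raise ValueError(f"unknown drugs {sorted(unknown)}; allowed: {DRUGS}")
        if len(set(drugs)) != len(drugs):
            raise ValueError("duplicate drugs in strategy")
        if len(drugs) > 3:
            raise ValueError("at most three drugs per strategy")
        if self.label is None:
            object.__setattr__(self, "label", "+".join(drugs) or "none")

    def __str__(self) -> str:
        return self.label


def combine_rrs(rrs: Iterable[float]) -> float:
    """Multiplicative interaction: the combined RR is the product."""
    out = 1.0
    for rr in rrs:
        if rr <= 0:
            raise ValueError("relative risks must be positive")
        out *= rr
    return out


def rr_vs_no_treatment(
    drug: str,
    params,
    variant: Optional[str] = None,
) -> dict[str, float]:
    """Per-outcome relative risk of one drug versus no treatment.

    Chains the drug's head-to-head comparisons down to the CCB anchor; a
    missing link raises ``KeyError`` naming the comparison.
    """
    if drug not in _CHAINS:
        raise ValueError(f"unknown drug {drug!r}")
    out = {}
    for outcome in OUTCOMES:
        rr = params.effect("ccb_vs_placebo", outcome, variant).rr
        for comparison in _CHAINS[drug]:
            rr *= params.effect(comparison, outcome, variant).rr
        out[outcome] = rr
    return out


def strategy_effective_rr(
    strategy: Strategy,
    params,
    variant: Optional[str] = None,
    adherence: float = 1.0,
) -> dict[str, float]:
    """Per-outcome RR vs no treatment for a whole strategy.

    Single-drug RRs combine multiplicatively across the strategy's drugs.
    ``adherence`` optionally shrinks each drug's risk *reduction* toward the
    null: ``rr -> 1 - adherence * (1 - rr)``.
    """
    out = {o: 1.0 for o in OUTCOMES}
    for drug in strategy.drugs:
        drug_rr = rr_vs_no_treatment(drug, params, variant)
        for outcome in OUTCOMES:
            rr = drug_rr[outcome]
            if adherence != 1.0:
                rr = 1.0 - adherence * (1.0 - rr)
            out[outcome] = combine_rrs([out[outcome], rr])
    return out


# primary-event name -> treatment outcome acted upon
_EVENT_OUTCOME = {
    "ami": "ami",
    "stroke": "stroke",
    "cvd_death": "total_mortality",
    "heart_failure_event": "heart_failure",
    "angina": "angina",
}


def apply_treatment(
    baseline: Mapping[str, float],
    eff: Mapping[str, float],
    flags,
) -> dict[str, float]:
    """Multiply primary-event probabilities by the strategy's RRs.

    Heart-failure and angina probabilities are only modified when the
    scenario flag enables those outcomes; ``other_death`` is never touched.
    Results are clipped to [0, 1].
    """
    out = {}
    for event, p in baseline.items():
        outcome = _EVENT_OUTCOME.get(event)
        if outcome is None:
            out[event] = p
            continue
        if outcome in ("heart_failure", "angina") and not flags.include_hf_angina_efficacy:
            out[event] = p
            continue
        out[event] = min(1.0, max(0.0, p * eff.get(outcome, 1.0)))
    return out


def annual_treatment_cost(strategy: Strategy, year_on_treatment: int, params) -> float:
    """Drug acquisition plus one GP-monitoring stream per patient-year.

    Monitoring follows the thiazide visit schedule when a thiazide is in the
    strategy, otherwise the statin schedule stands in as the generic
    monitoring cost; it is charged once regardless of the number of drugs.
    """
    if year_on_treatment < 1:
        raise ValueError("year_on_treatment starts at 1")
    if not strategy.drugs:
        return 0.0
    total = 0.0
    for drug in strategy.drugs:
        total += params.cost(_DRUG_COST_LABEL[drug])
    stream = "thiazide" if "thiazide" in strategy.drugs else "statin"
    when = "first_year" if year_on_treatment == 1 else "later_years"
    total += params.cost(f"gp_visits_{stream}_{when}")
    return total
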
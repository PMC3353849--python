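"""Discounting and the decision framework: ICER, INHB, strategy ranking.

Incremental cost (IC) and incremental effect (IE, life years) of a strategy
against a comparator are summarised either as the incremental
cost-effectiveness ratio ``ICER = IC / IE`` (with dominance flags when the
signs make the ratio misleading) or as the incremental net health benefit

    INHB = IE - IC / T

at a willingness-to-pay threshold ``T`` (default 62,000 euro per life
year). Against a common baseline, the strategy with the highest INHB is the
most cost-effective; a negative INHB means the resources would buy more
health elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .markov_engine import CohortTrace, PatientProfile
from .treatment import Strategy

__all__ = [
    "DOMINANT",
    "DOMINATED",
    "UNDEFINED",
    "StrategyResult",
    "ComparisonResult",
    "discount_factor",
    "icer",
    "inhb",
    "compare",
    "rank_strategies",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


def discount_factor(cycle_index: int, rate: float) -> float:
    """Present-value weight ``(1 + rate) ** -cycle_index``; cycle 0 is
    undiscounted."""
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if cycle_index < 0:
        raise ValueError("cycle_index must be nonnegative")
    return (1.0 + rate) ** (-cycle_index)


def icer(ic: float, ie: float) -> Union[float, str]:
    """IC/IE, or a dominance flag when the ratio would mislead."""
    if ic < 0 and ie > 0:
        return DOMINANT
    if ic > 0 and ie < 0:
        return DOMINATED
    if ie == 0:
        return UNDEFINED
    return ic / ie


def inhb(ie: float, ic: float, threshold: float) -> float:
    """Incremental net health benefit ``IE - IC / T`` in life years."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return ie - ic / threshold


@dataclass(frozen=True)
class StrategyResult:
    """Lifetime discounted/undiscounted cost and life expectancy for one
    strategy and patient profile."""

    strategy: Strategy
    profile: PatientProfile
    cost_disc: float
    cost_undisc: float
    ly_disc: float
    ly_undisc: float

    @classmethod
    def from_trace(
        cls, trace: CohortTrace, strategy: Strategy, profile: PatientProfile
    ) -> "StrategyResult":
        return cls(
            strategy=strategy,
            profile=profile,
            cost_disc=trace.total_cost_disc,
            cost_undisc=trace.total_cost_undisc,
            ly_disc=trace.total_ly_disc,
            ly_undisc=trace.total_ly_undisc,
        )


@dataclass(frozen=True)
class ComparisonResult:
    strategy: Strategy
    baseline: Strategy
    ic: float
    ie: float
    icer: Union[float, str]
    inhb: float
    threshold: float


def compare(
    result: StrategyResult,
    baseline: StrategyResult,
    threshold: float,
    discounted: bool = True,
) -> ComparisonResult:
    if result.profile != baseline.profile:
        raise ValueError("comparison requires a common patient profile")
    if discounted:
        ic = result.cost_disc - baseline.cost_disc
        ie = result.ly_disc - baseline.ly_disc
    else:
        ic = result.cost_undisc - baseline.cost_undisc
        ie = result.ly_undisc - baseline.ly_undisc
    return ComparisonResult(
        strategy=result.strategy,
        baseline=baseline.strategy,
        ic=ic,
        ie=ie,
        icer=icer(ic, ie),
        inhb=inhb(ie, ic, threshold),
        threshold=threshold,
    )


def rank_strategies(
    results: Sequence[StrategyResult],
    baseline: Strategy,
    threshold: float,
) -> list[ComparisonResult]:
    """Compare every non-baseline strategy to the common baseline and sort
    by INHB (descending); ties break on lower cost, then label."""
    profiles = {r.profile for r in results}
    if len(profiles) != 1:
        raise ValueError("all results must share one patient profile")
    base = [r for r in results if r.strategy == baseline]
    if not base:
        raise ValueError(f"baseline strategy {baseline.label!r} not among results")
    base_result = base[0]
    comparisons = [
        compare(r, base_result, threshold)
        for r in results
        if r.strategy != baseline
    ]
    cost = {c.strategy: c.ic for c in comparisons}
    comparisons.sort(key=lambda c: (-c.inhb, cost[c.strategy], c.strategy.label))
    return comparisons
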
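# Methods

## The decision problem

`cardiocea` estimates the lifetime cost-effectiveness of generic
antihypertensive drugs — thiazide, ACE inhibitor, calcium channel blocker
(CCB), angiotensin receptor blocker (ARB) and beta blocker, alone or in
combinations of two or three — for the primary prevention of cardiovascular
disease (CVD), from a health-care payer perspective, with life years as the
effect measure and 2011 euro as the cost unit.

## Cohort model

A deterministic Markov cohort model follows people who are free of CVD from
a start age (40, 50, 60 or 70 by default, both sexes) in annual cycles
until everyone is dead or 100 years old. The nine health states are:
disease-free; post-AMI, post-angina and post-stroke-without-sequelae
(asymptomatic CVD); moderate and severe stroke sequelae; heart failure; and
two absorbing death states (cardiovascular and other causes).

**Primary events.** Disease-free individuals experience first-ever AMI,
stroke, angina, heart failure or CVD death at age- and sex-specific annual
baseline rates, converted to probabilities as `1 - exp(-rate)`, plus death
from other causes. Competing risks within a cycle are left untouched when
they sum to at most one (the remainder is the stay-put probability) and are
proportionally rescaled otherwise, with a counter recording rescalings.

**First year after an acute event.** The cycle in which an event occurs is
its first year: the event-conditional secondary risks apply (e.g. stroke
case fatality 0.338, moderate sequelae 0.072, severe sequelae 0.169; AMI
case fatality by age band; early reinfarction; secondary heart failure).
AMI splits into STEMI and non-STEMI with a configurable mix (default
50/50); where both a six-month and an in-hospital probability are printed
for the same secondary event, only the larger six-month figure is used to
avoid double counting. Secondary chains are resolved within the cycle to a
depth of two; deeper nonfatal chains are truncated (their probability mass
is a few per mille of an already-rare branch), while case fatality is
always applied. Deaths occurring as event case fatality are routed to the
cardiovascular death state and charged the in-hospital cardiac death cost.

**Worst-state memory.** After the first year the patient carries the risks
and costs of the most severe state reached:
severe sequelae > moderate sequelae > heart failure > asymptomatic
post-event states > disease-free, with ties among the asymptomatic states
broken by the most recent event. A new event in a patient whose memory is
more severe (e.g. an AMI in a stroke-sequelae patient) adds its one-time
costs and first-year risks once, after which the patient reverts to the
sequelae state.

**Later years.** Event probabilities in chronic states are the baseline
age-specific probability multiplied by a state-specific relative risk
versus healthy subjects, capped at one. Heart-failure mortality is specific
to the second, third and later years after onset, implemented as a
three-level tunnel clock; all other states distinguish only first year
versus later. Secondary heart failure resolves within 6-12 months with
probability 0.5, in which case the patient reverts to the prior worst
state; the branch is decided at event time, which is equivalent in
distribution and keeps the expanded state space at eleven states.
Heart-failure "worsening" events charge the worsening cost and leave the
tunnel clock running; their mortality is already carried by the
year-specific dying rows.

**Accounting.** Life years and per-year state, drug and monitoring costs
are credited to the cohort alive at cycle start without half-cycle
correction; one-time event costs are discounted at the cycle of the event.
Costs and effects are both discounted at 4% per year
(`(1 + r)^-cycle`), cycle 0 undiscounted. At the age-100 boundary the
remaining survivors move to death from other causes. By default
primary-prevention drug costs continue for every survivor (configurable to
stop on leaving the disease-free state); treatment effects apply to primary
events only.

## Treatment effects

Only CCB has a placebo-controlled anchor; other drugs are connected to it
through head-to-head relative risks, multiplied along the chain
(`thiazide -> ACE -> CCB -> placebo`). Combinations interact
multiplicatively: the combined RR is the product of the single-drug RRs.
The total-mortality RR is applied to the CVD-death primary event only,
never to other-cause death, because the model separates the two and
antihypertensives plausibly act on cardiovascular death. In the base case
heart-failure and angina primary events receive no treatment effect (softer
trial endpoints); a scenario flag enables them. The base-case head-to-head
evidence uses the meta-analysis variant excluding African-American
participants; the all-included variant is a scenario.

The CCB-vs-placebo anchors and the ARB/beta-blocker head-to-head RRs are
not part of the packaged evidence tables; the shipped values in
`data/treatment_effects_synthetic.csv` are clearly labelled synthetic
placeholders of realistic magnitude (e.g. stroke RR 0.66 for CCB vs
placebo) and must be overridden with real estimates for any substantive
use.

## Synthetic baseline incidence

National registry incidence curves are not redistributable, so baseline
rates are generated as Gompertz hazards `a * exp(b * (age - 40))` per event
and sex (female rates a fixed ratio of male rates), ages 30-100. The
defaults (e.g. male AMI `a = 0.001`, `b = 0.085`, female ratio 0.5; other
cause mortality `a = 0.0012`, `b = 0.095`) imitate the qualitative shape of
a Northern-European population — incidence roughly doubling every 8-10
years, male excess for coronary events — and were fixed once when the
generator was written. They reproduce realistic life expectancies
(about 25 undiscounted years for an untreated 50-year-old man) but make no
numerical claim about any registry; passing tests therefore demonstrate the
correctness and internal consistency of the machinery, not agreement with
national statistics. Optional seeded log-normal jitter can roughen the
curves; it is off by default so generation is byte-reproducible.

## Calibration

The untreated model's CVD-specific mortality (CVD deaths per person-year by
sex and decade of age) is matched to external targets by per-(sex, decade)
multiplicative factors on the baseline CVD rates — primary events plus CVD
death; the event-conditional evidence tables are never rescaled, and
neither is other-cause mortality. A ratio update
`factor <- factor * target / achieved` converges in a handful of
iterations because band mortality is nearly proportional to the band's
factor. Synthetic targets are produced by running the untreated model on
rates scaled by a known distortion, so the calibration stage can be tested
against exact ground truth; recovery is accurate to about 1e-5 at a 1e-5
convergence tolerance. The procedure is a reconstruction: it implements the
stated goal, not a published algorithm.

## Decision framework

For a strategy versus a comparator with incremental cost IC and incremental
effect IE: `ICER = IC/IE` (flagged *dominant* when IC < 0 and IE > 0,
*dominated* in the opposite quadrant, *undefined* at IE = 0), and
`INHB = IE - IC/T` in life years at threshold T = 62,000 euro per life
year. Against a common baseline, strategies are ranked by INHB. Note that
the textbook shorthand "INHB > 0 iff dominant or ICER < T" holds whenever
IE > 0 (and its converse for dominated pairs) but fails in the
cheaper-and-worse quadrant, where a large saving can outweigh a small
health loss; tests assert the identity on its valid domain.

## Probabilistic sensitivity analysis

Each uncertain input carries a parametric distribution fitted from its
point estimate and 95% interval, treating the interval as a symmetric
normal CI (`SE = width / (2 * 1.96)`): beta by the method of moments for
probabilities, log-normal for relative risks with `mu = ln(point)` (the
median equals the point estimate), gamma by moments for costs. Rows
printed without an interval stay fixed rather than being given invented
uncertainty; this includes all cost items by default (an opt-in
coefficient-of-variation setting attaches gamma distributions to costs)
and the age-banded AMI case-fatality rows, whose single repeated interval
in the source table is unusable. Baseline incidence rates are not sampled.

Monte Carlo runs draw one parameter set per iteration and evaluate every
strategy on it (common random parameters). The reference iteration count is
10,000; the test suite uses 20-500 iterations, which is sufficient for the
determinism and qualitative checks it performs. CEACs report the fraction
of iterations in which each strategy maximises `ly - cost/t` over a
threshold grid (default 0 to 150,000 euro in 2,500 steps; at t = 0 the
cheapest strategy wins); exact ties split the win equally, so the
probabilities sum to one at every threshold.

## Verification

The cohort engine is cross-checked against an individual-level
microsimulation that samples the identical per-(age, state) outcome-branch
distributions (100,000 individuals agree with the cohort expectation within
three standard errors on discounted life years and costs). Invariants under
test include occupancy conservation (1e-9), monotone dead-state occupancy,
zero survivors at the horizon, discounting identities at rate zero, CEAC
column sums, and the INHB/ICER sign identities on their valid domain.

## Known limitations

No combined health states (e.g. heart failure plus stroke sequelae), no
intermittent claudication, no side-effect costs or adherence dynamics (an
optional adherence multiplier on treatment RRs exists but defaults to 1),
no QALY weighting, and no efficiency-frontier pruning beyond INHB ranking.
Relative treatment effects are assumed constant for life. The synthetic
baseline and the synthetic anchor/ARB/beta-blocker effects mean the shipped
numbers illustrate the method; policy conclusions require real inputs.
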
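# cardiocea

A lifetime Markov cohort model for the cost-effectiveness of generic
antihypertensive drugs — thiazide, ACE inhibitor, calcium channel blocker
(CCB), angiotensin receptor blocker and beta blocker, alone or in two- and
three-drug combinations — in the primary prevention of cardiovascular
disease. It is aimed at health economists and HTA analysts who want a
tested, scriptable implementation of the full pipeline: cohort simulation,
treatment-effect chaining, discounted cost/life-year accounting, ICER/INHB
decision rules, calibration to CVD mortality, and probabilistic sensitivity
analysis with cost-effectiveness acceptability curves.

## The model in brief

A cohort enters disease-free at age *a₀* and moves through nine health
states in annual cycles until dead or 100: disease-free, asymptomatic CVD
(post-AMI / post-angina / post-stroke), moderate and severe stroke
sequelae, heart failure, and death from cardiovascular or other causes.
Primary events strike at age- and sex-specific baseline rates; the first
year after an acute event carries event-conditional secondary risks
(case fatality, early reinfarction, secondary heart failure); later years
multiply baseline risks by state-specific relative risks. Patients keep the
risks and costs of the worst state they have reached.

Treatment multiplies primary-event risks by per-outcome relative risks,
anchored on CCB-vs-placebo and chained through head-to-head comparisons;
combinations interact multiplicatively (RRs 0.9 and 0.8 combine to 0.72, a
28% relative risk reduction). Costs (2011 €, converted at NOK 8.01/€) and
life years are discounted at 4% per year. Strategies are judged by the
incremental net health benefit

    INHB = IE − IC / T,    T = €62,000 per life year,

so a treatment gaining 1.3 life years at an incremental €31,000 has
INHB = 1.3 − 31,000/62,000 = 0.8 life years.

Baseline incidence is generated synthetically (Gompertz hazards with a
registry-like age/sex structure), and the CCB-vs-placebo anchors plus
ARB/beta-blocker head-to-head effects are labelled synthetic placeholders —
both must be replaced with real inputs for substantive use. See
`docs/methods.md` for the full model description and its limitations.

## Worked example

```python
import cardiocea as cc
from cardiocea.model import NO_TREATMENT
from cardiocea.treatment import Strategy

model = cc.CvdPolicyModel(
    profiles=[cc.PatientProfile("male", 70), cc.PatientProfile("male", 50)],
    strategies=[NO_TREATMENT, Strategy(drugs=("ccb",)),
                Strategy(drugs=("ccb", "thiazide"))],
)
results = model.fit()
print(results.summary())
```

```
Lifetime cohort results (per patient)
============================================================
 sex  start_age     strategy  cost_disc  cost_undisc  ly_disc  ly_undisc
male         70         none 40,089.744   60,721.642    8.381     10.517
male         70          ccb 36,539.954   55,810.767    8.625     10.903
male         70 ccb+thiazide 33,026.169   50,933.687    8.799     11.185
male         50         none 34,169.136   87,641.202   15.673     25.318
male         50          ccb 31,538.346   80,660.338   15.874     25.851
male         50 ccb+thiazide 28,370.794   73,250.635   16.013     26.235

INHB vs no treatment at T = 62,000 euro/LY
------------------------------------------------------------
sex          male     
start_age      70   50
inhb_vs_none          
ccb          0.30 0.24
```

Under the synthetic inputs, CCB for a 70-year-old man is *dominant* — it
saves €3,550 in discounted lifetime costs (fewer strokes and infarctions
outweigh drug and monitoring costs) while adding 0.243 discounted life
years, for an INHB of 0.30 life years:

```python
c = results.compare(Strategy(drugs=("ccb",)), NO_TREATMENT,
                    cc.PatientProfile("male", 70))
print(f"IC={c.ic:.0f} IE={c.ie:.3f} ICER={c.icer} INHB={c.inhb:.3f}")
# IC=-3550 IE=0.243 ICER=dominant INHB=0.301
```

`model.fit_psa(n_iter=10_000, seed=1)` propagates parameter uncertainty and
`.ceac()` returns the acceptability curves. The command line mirrors the
library: `cardiocea synth`, `cardiocea calibrate`, `cardiocea run --config
config.yaml` (full pipeline with CSV outputs and a MANIFEST) and
`cardiocea psa`.

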
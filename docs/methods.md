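# Methods

## Model overview

`demodep` projects a closed-form-free, individual-level population model in
discrete 5-year steps. The state is a weighted case file: each case carries
a 5-year age band (0–4 … 100+, top-open), sex, an ordered educational
attainment, a labour-force status and a positive weight (persons per case).
Events are Bernoulli/Poisson experiments per case; the model is *time-based*
(it simulates everyone over one step, then repeats), *discrete-time* (no
within-step timing) and *stochastic* (a transition occurs when its
probability exceeds a fresh uniform draw).

### Event order and ageing

Each step applies mortality, education shifts, emigration, immigration,
fertility and labour-force assignment, in that order — emigration rates act
only on mortality survivors, newborns are not exposed to the step's
emigration, and immigrants receive a labour-force status with everyone else.

Ages are incremented immediately after mortality rather than at the end of
the step. Survivorship ratios apply to the band occupied at *t* (that is
what a 5-year survival ratio means), while the education, emigration,
immigration and fertility schedules are keyed to the band *attained at
t+5* — the natural reading of "the cohort is broken down at the age of
15–19". The two conventions are arithmetically identical up to a relabeling
of schedule rows; incrementing early keeps every intermediate frame valid
under the data-model invariants (a cohort entering 15–19 receives education
and a labour-force status within the same step, so no working-age case ever
carries the child placeholders).

### Common random numbers

Every draw is a pure function of (global seed, individual id, event,
period), computed with a vectorised SplitMix64-finalizer hash
(`demodep.streams`). Consequences, all tested:

- identical seeds reproduce a run exactly;
- two scenarios differing only in fertility give the same outcome to every
  individual born before the start — the age 25+ structures at 2040 under
  TFR 0.8 and 1.7 are *bit-identical*, not merely close;
- newborn ids are hashes of (mother id, period, birth order), so even
  children common to both scenarios stay aligned.

Birth counts per woman per step are Poisson with mean 5 × TFR × shape(age),
inverted from a single uniform via the CDF (checked against the scipy
Poisson CDF in tests). A Poisson rather than a Bernoulli allows multiple
births per 5-year window, which a high-fertility scenario needs; capping at
one would bias it downward. Newborn sex uses a configurable sex ratio at
birth (default 1.05 males per female) and newborns face a partial-period
survivorship ratio from the schedules (full survival if the table is
absent).

### Base-population synthesis

Aggregate cell counts are converted to cases as
`n = max(round_half_up(count × fraction), 1)`, with cells below the
oversampling threshold (default 10,000 persons) topped up to a floor of 20
cases — capped at one case per person so a 100% fraction degenerates to a
unit-weight census. Weights are `count / n` exactly, making the weighted
frame match the aggregates cell by cell with zero rounding leakage. The
builder is fully deterministic; reproducibility of the base file seemed
worth more than stochastic rounding's unbiasedness at the margin of a
single case per cell. Immigrant cases follow the same rules, with ids drawn
from a per-period block that is a pure function of the period.

## Calibration models

**Participation.** A logit per sex: quadratic in the centred, scaled band
midpoint x = (mid − 45)/5, education as a categorical with full education ×
x and education × x² interactions (reference: upper secondary). The coding
is stored on the parameter object. Fitting uses the statsmodels binomial
GLM; pre-checks reject a missing sex stratum and any sex × education
stratum with a constant outcome (complete separation), naming the stratum.
Max-rescaled (Nagelkerke) R² and the c-statistic are computed per sex and
logged as diagnostics — they characterise fit on whatever survey is
supplied and are not contract values. Outside the 15–74 survey window the
model is not evaluated: the engine assigns rate 0 (inactive) to 75+ rather
than extrapolating a quadratic beyond its support, and children are never
drawn. Parameters are held constant over the projection, so aggregate
participation changes are composition effects by construction.

**Productivity weights.** A Poisson GLM with log link on the wage of active
respondents with additive education, age-band, sex and survey-year
controls. The response is continuous; the estimator is the standard
quasi-likelihood solution for a log-linear mean, which is exactly what the
weights need — no distributional claim is made. Weights are
W<sub>e</sub> = exp(β<sub>edu</sub>[e]) with the reference level at 0 by
coding, so W(reference) = 1 *exactly*; recentring to another reference
divides all weights through. Year effects never enter the weights (tested
by relabeling invariance). Fits are unweighted, with a `weight_col` hook
for surveys that need sampling weights.

## Indicators

ADR uses band codes only. LFDR counts every non-active person — children
and the very old included — in the numerator. PWLFDR divides the same
unweighted inactive count by Σ W<sub>e</sub>A<sub>e</sub>; with unit
weights it equals the LFDR exactly (tested as an identity, not to a
tolerance). All three are invariant to uniform weight rescaling. The
pyramid summary collapses the ladder around the reference level (below →
low, reference → medium, above → high); the child placeholder maps to low.

## Synthetic world

The generator supplies study conditions, not a replica of any real country:

- **Pyramid**: a Gaussian bulge centred at 45 (spread 22 years), a child
  deficit factor 0.75 and an exponential old-age taper — a stylised ageing
  population in which the ADR crossover mechanics are visible.
- **Education**: softmax over ladder scores with a cohort gradient (default
  0.8) that makes younger cohorts more educated, a constant female shift,
  and a period gradient (0.15 per step) that keeps raising new entrants'
  attainment. At 15–19 postsecondary mass is folded into upper secondary
  (nobody has completed postsecondary by 19), so cohort-invariance
  properties are stated for ages 20+.
- **Mortality**: Gompertz hazard 5e-5·exp(0.085·age), improving 1.5% per
  step, graded by education (×1.30 for no education down to ×0.80 for
  postsecondary) and sex (×0.85 female).
- **Fertility**: a bell over 15–49 peaking at 20–29, normalised so
  Σ shape × 5 = 1; the scenario TFR scales it exactly.
- **Migration**: young-adult-peaked emigration (0.4% per 5 years at the
  mode) against a fixed low immigration volume (500 persons per period per
  million base population, young and educated) — net migration is negative
  under defaults, and emigrant *counts* differ between fertility scenarios
  because the exposed populations do.
- **Survey**: ages 15–74 drawn from the pyramid, activity Bernoulli at the
  true logit probability, wages Poisson at the true log-linear mean around
  a reference monthly wage of 1,500, with generating premia spanning
  exp(−1.0) ≈ 0.37 to exp(0.7) ≈ 2.01. A gamma-overdispersion option
  exists for estimator-robustness checks.

What passing tests on this world show — and what they do not: parameter
recovery, conservation accounting, scenario comparability and the
qualitative ADR crossover are properties of the *machinery* and hold
regardless of inputs; levels and dates (e.g. the crossover around 2045 in
the examples) are properties of the synthetic schedules and will differ for
real estimates. Real survey data additionally carry sampling design,
measurement error and wage censoring that the generator does not emulate.

## Problem sizes and numerics

The test suite and examples run at 20,000–100,000 cases and horizons of
2–11 steps, sizes at which the binomial envelopes (±3 SD) and the
between-seed dispersion bound (<2% relative on the final-period LFDR at
~60,000 cases over four seeds) are sharp; at the paper-scale 700,000 cases
the same dispersion shrinks by roughly √12, which is why a single run is
treated as representative. Degenerate inputs are rejected eagerly: negative
counts, unnormalised fertility shapes, outgoing transition probabilities
above 1, downward education moves, missing strata for an occupied cell,
zero denominators in every ratio. Education entry distributions force their
final cumulative bin to exactly 1.0 to guard against float undershoot
leaving a new adult unassigned.

## Open choices made here

- The education ladder defaults to five categories (no education, primary,
  lower secondary, upper secondary, postsecondary); a six-level split of
  postsecondary is supported via `EducationLadder(levels=...)` and is a
  visible configuration, never a silent merge.
- Labour-force status is redrawn each period from the cross-sectional
  model; no state persistence and no lagged-fertility covariate (the
  fitted model uses age, sex and education only).
- The PWLFDR numerator is the plain inactive count — productivity weights
  apply to workers only.
- Immigrants below 15 follow the same education-entry rules as natives.

## Known limitations

No annual interpolation or continuous age; no internal migration or
regional detail; no household structure beyond the mother → newborn weight
link; no monetary translation of productivity weights; participation
parameters cannot vary over time. These are scope decisions, not accidents
of implementation.
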
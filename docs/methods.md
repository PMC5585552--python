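# Methods

## The model

`npsim` implements an individual-based (Monte Carlo) model of sex
partnering, conception and demography in a female population, built to
study whether two genetically observable quantities — the **nonpaternity
ratio** and the **half-siblings ratio** — can serve as objective,
survey-free measures of extramarital sex, the behavior believed to drive
partnership concurrency and hence STI/HIV transmission in settings such as
Sub-Saharan Africa.

Women are the simulated units. Each woman is born, ages, dies, forms and
dissolves marital and nonmarital partnerships, becomes pregnant, and gives
birth. Discrete time advances in steps of `time_step_days` (default 7
days); every hazard `r` per year becomes a per-step event probability
`1 − exp(−r·Δt)`. Within a step the phases are: deliver due births, apply
mortality, update partnerships, attempt conceptions.

Partnership dynamics, for women above age 15:

* **Marriage** forms at hazard α (default 0.12/y, the value a least-squares
  fit of the two-state closed form
  `p(a) = α/(α+μ)·(1 − e^{−(α+μ)(a−15)})` recovers from DHS-style
  age-specific married prevalence; `fit_marriage_rate` performs this fit),
  dissolves at hazard μ_marital = 1/20 y, and is strictly monogamous.
  Remarriage uses the same α.
* **Nonmarital partnerships** form at individual rates λ_p,i (premarital,
  for unmarried women) and λ_e,i (extramarital, for married women), drawn
  per woman from a Gamma distribution with the scenario's mean and variance
  (degenerate at variance 0). Formation rates are modulated by a
  time-dependent factor h(t) and an age multiplier; partnerships dissolve
  at μ_casual = 2/y (6-month mean duration). The episode class recorded in
  the log is frozen at formation.
* A new **marriage supplants ongoing premarital partnerships** (they
  dissolve at the marriage date). This keeps "extramarital rate 0 ⇒ no
  nonpaternity" exact: otherwise premarital partners carried into a
  marriage would father nonpaternity births even with no extramarital
  partnering. Divorce, by contrast, does not end an ongoing extramarital
  partnership; its logged class stays extramarital.

Conception: per step a woman's coital acts are Poisson with mean c(a)·Δt.
A married woman with at least one active nonmarital partner gives an
expected fraction φ_m of acts to her spouse, the rest split uniformly among
those partners; with no such partner all acts are marital; unmarried women
split acts uniformly among active partners. (Acts are drawn per channel by
Poisson thinning, which is distributionally identical to drawing the total
and splitting it multinomially.) Each act conceives with probability
`f(a)·(1 − Eff·C_v)` where f is age-specific fecundability, Eff condom
efficacy (0.90) and C_v class-specific condom coverage (unmarried 0.23,
marital 0.019, extramarital 0.074). Per channel the step conception
probability is `1 − (1 − p)^n`; if several channels succeed in one step
(rare at weekly resolution) the biological father is chosen uniformly among
them. Gestation is `max(1, round(N(267, 10²)))` days; no conception can
occur while gestating. Twins are not modeled.

Bookkeeping at conception (not at birth — the extramarital act and the
mother's marital status exist at conception): the putative father is the
husband of record, and the child is a **nonpaternity event** iff the mother
was married and the biological father differs from the husband. Sex is
assigned 1:1; girls enter the female population at birth and become
eligible for partnering at 15 y, which makes multi-century runs
self-sustaining. Boys are tracked in the registry for mortality only. Male
partners are identity tokens (no male-side dynamics): fathers need only be
distinguishable for nonpaternity and half-sibling bookkeeping, and each new
nonmarital partnership gets a fresh token (no partner re-meeting).

## Measures

With the birth registry and episode log, computed at annual censuses
(undefined ratios are NaN, never 0):

* `NPR(t)` — nonpaternity births / all births over the last 12 months.
* `NPR_x(t)` — among individuals aged [x, x+1) and **alive** at t, the
  fraction that are nonpaternity events. Without child mortality
  `NPR_x(t) = NPR(t − x)` exactly; with it, survival is independent of
  paternity status by construction, so the identity holds in expectation.
* `EPR(t)` — among women with a marital episode overlapping the last 12
  months: extramarital episodes overlapping the window / all their episodes
  overlapping the window (a marriage counts as one episode per window).
* `HSR(t)` — fraction of unordered same-mother child pairs with different
  biological fathers, over children born by t (dead or alive). **Sibships
  are restricted by default to children conceived within a marriage**
  (those with a putative father): the measure targets partnership turnover
  among married women — extramarital fathering and remarriage. Including
  premarital births (`scope="all"`) makes the ratio track the premarital
  rate instead and largely decouples it from EPR; a child-level variant
  (children with ≥1 half-sibling / children with ≥1 sibling) is also
  available.

The 10-year moving-average smoother is centered, truncates at the edges and
ignores NaNs.

## Statistics

Correlation analyses pool (EPR(T−1), measure(T)) pairs across runs and
annual censuses — the one-year lag accommodates gestation — and report
Pearson's r with a Fisher-z interval, `tanh(atanh r ± z*/√(n−3))`. Pooled
annual pairs within a run are autocorrelated, so by default the interval
uses n = number of runs rather than the pooled pair count (with n = 100
runs this reproduces intervals like 0.79 → (0.703, 0.854)); the literal
pooled-n mode is available.

## Default parameters and stand-in schedules

Behavioral and demographic scalars (marriage rate 0.12/y, 20-y marriages,
6-month casual partnerships, premarital rate mean 0.32/y var 0.0087,
extramarital mean 0.0088/y var 0, φ_m 0.7, condom coverage/efficacy,
gestation N(267, 10²)) describe a Kenya-like DHS-derived population.
Scenario sweeps draw premarital mean/var uniformly from [0,1]/[0,2] and
extramarital mean/var from [0,0.5]/[0,1], the across-country ranges for
Sub-Saharan Africa.

The three age schedules ship as editable stand-ins (step functions over
(age, value) knots):

* **Coital frequency**: 96 acts/y at 15–25 declining to 36/y at 49.
* **Mortality**: abridged life-table shape with elevated infant/child
  mortality (q₀ ≈ 0.14, e₀ ≈ 45–50), a pre-transition regime.
* **Effective fecundability**: 0.0037/act at 20 declining to 0 at 50.
  This is deliberately an *effective* schedule, not raw biological per-act
  fecundability: the model has no lactational amenorrhea, postpartum
  abstinence or non-condom contraception, so raw literature values
  (~0.02–0.03/act) would imply completed fertility above 12 births/woman
  and order-of-magnitude population growth over the 150–201-year horizons
  the experiments need. The shipped values were calibrated once so that
  completed fertility is ≈ 3 births per woman surviving to adulthood and
  the default population is near-stationary (within a few percent over 120
  years). Correlation-based results are insensitive to the fertility level;
  absolute NPR levels (the φ_m sweep) do depend on these stand-ins.

The nonmarital age multiplier defaults to 1 at all ages (no age calibration
of nonmarital rates is shipped); h(t) defaults to the constant 1.

## Experiments

* **NPR↔EPR** and **HSR↔EPR**: n runs with sweep-drawn nonmarital rates,
  φ_m = 0.7, 50-year burn-in, annual censuses thereafter; pooled r between
  the measure at T and EPR at T−1.
* **Historical back-casting**: h(t) follows either a *steady decline*
  (linear from 1.0 to 0.3 over 10 years, then a plateau — the post-HIV
  behavior-change narrative) or a *transient drop* (down in 5 years,
  back up in 5). The floor corresponds to the self-reported (Kenya-like)
  rates, so base nonmarital rate means are divided by the floor level
  (0.3) and h ramps 1.0 → 0.3. The decline starts 40 years before the end
  of the run so the change lies inside the 0–50-year back-cast window.
  At the final census T the age profile NPR_x(T), x = 0..50, is paired with
  EPR(T−x−1); r is reported raw and after smoothing both the EPR history
  (over time) and the NPR_x profile (over age) with the 10-year moving
  average. A single final-census profile per run is used (the pooling of
  intermediate censuses is configurable but adds strongly overlapping,
  autocorrelated pairs).
* **φ_m sweep**: 0.1 to 0.9 in steps of 0.1 at fixed base rates; each run
  summarised by its mean NPR over censuses, each φ by the across-run mean
  and a 95% t-interval. Mean NPR decreases in φ_m (fewer extramarital acts,
  fewer nonpaternity conceptions).

## Problem sizes

The package's reference checks run the experiments at desk scale: 30 runs
of 2,000 women for the sweep experiments (80-year horizon = 50 burn-in +
30 measurement years) and 30 runs of 4,000 women for the historical
back-casting (120 years = 50 + 70) — the age-specific nonpaternity
numerators are sparse (a handful of events per age band), so the
historical runs use the largest population the reference-run budget
allows. At 2,000 women the
annual birth cohort is ~100, so single-year measures carry binomial noise
that dilutes *pooled* correlations relative to 20,000-women runs (e.g. the
NPR↔EPR pooled r is ≈ 0.67 at desk scale while the between-run correlation
of run means is ≈ 0.95); the acceptance bands used in the tests inflate the
printed confidence intervals accordingly. Scale enters only through
configuration — population, number of runs and horizon are ordinary
parameters, and the full-scale configuration is the default
`ScenarioParams`.

## Numerical and design choices

* Event ordering within a step (births, deaths, partnerships, conceptions)
  uses start-of-step state snapshots; a marriage formed in a step cannot
  dissolve in that step.
* Formation/dissolution probabilities are exact exponential-waiting-time
  step probabilities, so halving the step changes dynamics only at
  O(Δt²).
* Initial populations draw ages from the stationary pyramid of the
  mortality schedule and marital status from the two-state closed form, so
  burn-in converges quickly.
* Years are 365 days throughout.
* The gestation draw is clamped at ≥ 1 day (a negative N(267,10) draw is a
  >26σ event; the clamp is defensive).
* Women above `max_fertile_age` (49) keep partnering but no longer
  conceive.
* `fit_marriage_rate` uses bounded scalar minimisation on [0, 10]/y; for
  asymptote-only targets it returns the smallest optimum found by the
  bounded search, and an identically-zero target returns exactly 0.

## What the generator does not emulate

Synthetic populations here have no male-side partnership constraints, no
polygyny, no migration, no paternity-test error, no abortion, no
breastfeeding amenorrhea, and fertility/mortality schedules are stylised
stand-ins rather than fitted life tables. Passing tests therefore show that
the *measures track extramarital partnering within this model's world*;
they do not validate the absolute level of nonpaternity expected in any
real population, which depends on the un-modeled factors above.

## Known limitations

* HSR accumulates over all births up to t, so it responds slowly to recent
  behavior change; it is a cumulative, not a current, measure.
* At small populations the NPR_x numerators are sparse (0–2 events per age
  band), making the raw historical correlations heavily noise-diluted —
  the motivation for the moving-average smoothing.
* The effective-n choice for Fisher intervals (n = runs) is a modeling
  judgment about autocorrelation, not an exact correction.
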
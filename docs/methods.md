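# Methods

## Model structure

A four-state cohort Markov model — hypertension (HTN), acute CVD,
stable CVD, dead — with 1-year cycles from age 50 to a terminal age of
100 inclusive (51 cycles; the terminal age's death probability is
forced to 1, so the live states are empty at model end and the horizon
is a true lifetime). The cohort starts entirely in HTN. Allowed
transitions: HTN → {HTN, acute, dead}; acute → {acute (recurrence),
stable, dead}; stable → {stable, acute (recurrence), dead}; dead is
absorbing. Acute survivors who do not recur stabilise — the acute state
self-loops only through recurrence.

Each (age, sex, arm) matrix is assembled from three annual
probabilities:

- **Acute event** `p_a`: a pluggable risk equation returns a k-year
  first-event risk from age, sex, SBP and smoking status; it is
  annualised under a constant hazard, `p₁ = 1 − (1−p_k)^{1/k}`. The
  cohort tracks fractions, not individuals, so smoking enters as a
  prevalence: the equation is evaluated for smokers and non-smokers
  separately, each annualised, and the two annual probabilities mixed
  by prevalence. Recurrence reuses the same probability (no suitable
  recurrent-event equation exists for this population, so history of
  CVD is assumed not to alter the annual event probability at a given
  age and sex).
- **Background death** `qₓ` from a life table of annual all-cause death
  probabilities by integer age and sex.
- **CVD-state death**: the excess CVD mortality rate (0.003/yr men,
  0.002/yr women) adds to background mortality on the hazard scale,
  `q = 1 − exp(−(−ln(1−qₓ) + r))`, which keeps the result a valid
  probability ≥ qₓ without ad-hoc truncation.

Competing risks within a row: death is computed first, the acute-event
probability is scaled by (1 − death), and the residual mass goes to the
stay/stabilise destination. Rows are row-stochastic by construction.

Rewards accrue end-of-cycle: cycle *t*'s cost/LY/QALY is the
post-transition occupancy dotted with per-state annual rewards,
discounted by (1+r)^−t at 3 %/year for both costs and effects (base
case). A half-cycle correction (mean of pre- and post-transition
occupancy) is available but off by default — the simplest convention,
and the one a 1-year-cycle lifetime model is least sensitive to. Both
discounted and undiscounted streams are always carried: a published
lifetime LY total of ~33 years from age 50 is arithmetically impossible
under 3 % discounting, so LY totals are conventionally read
undiscounted while costs and QALYs are discounted.

Covariates (SBP, smoking prevalence) are frozen at their 12-month trial
values per arm and sex while age advances — the trial's effect is
extrapolated for life, with no waning model stated. A configurable
effect-waning half-life (default infinite) decays the intervention
arm's covariates geometrically toward the comparison arm's for
scenario analyses.

Sexes are modelled separately (the risk tool is sex-specific, as are
SBP, smoking, utilities and excess mortality) and combined 0.5/0.5 by
default; the trial's sex composition is not published and the weight is
a config field.

## Parameters

All 38 model inputs live in a CSV table (`data/table1_params.csv`,
transcribed verbatim from the study's input-parameter table) as
(name, family, mean, SE):

- **Normal**: SBP by arm/sex, encounter frequencies.
- **Beta** (moment-matched: ν = m(1−m)/se² − 1, α = mν, β = (1−m)ν):
  smoking prevalences, utilities, CVD mortality rates.
- **Gamma** (shape = (m/se)², scale = se²/m): all unit costs and
  programme-cost components.
- **Fixed**: the comparison-arm female smoking rate (printed as
  "Fixed 0"). Discount rates are likewise fixed and live in
  `DiscountRates`, not the uncertain-parameter table.

A printed SE of exactly 0 on a non-fixed family (the female CVD
mortality rate) degrades to a point mass with a logged warning rather
than an error; it contributes a zero-width tornado bar and does not
vary in the PSA.

95 % ranges for one-way sensitivity use mean ± 1.96·SE for normal
parameters and the 2.5 %/97.5 % quantiles of the moment-matched
distribution for beta/gamma (quantiles respect the support; a normal
approximation could produce negative costs or utilities above 1).

PSA sampling is independent across parameters (no correlation structure
is published). Arm-specific parameters are separate table rows and so
are drawn per arm; arm-agnostic parameters are shared across arms
within a draw. Draw *i* is reproducible from (master seed, *i*) via
spawned child seeds.

## Costing

Limited societal perspective, 2021 VND (inputs are already
standardised; a CPI hook exists but ships as identity). Each encounter
costs its medical fee plus the setting's non-medical components
(travel, meals, other). Frequencies are encounters per person-year
conditional on occupying the state, and the three inpatient
frequencies are treated as additive expected admissions across levels
(expected-value costing), so:

- **Acute CVD**: Σ over central/provincial/district of inpatient
  frequency × (acute admission fee + inpatient non-medical).
- **HTN**: outpatient frequencies × hypertension visit fees at the
  printed levels (provincial, district).
- **Stable CVD**: outpatient frequencies × stable-CVD visit fees at the
  printed levels (central, provincial).

This mapping uses every printed unit cost exactly once; level/service
combinations without a printed fee (central hypertension, district
stable-CVD) contribute zero and are logged.

The programme cost has two modes: *trial* (design + implementation +
monitoring-and-evaluation = VND 4,000,000/person-year exactly) and
*scale-up* (implementation only, VND 426,471 ≈ 430 thousand). It
accrues in the HTN state of the intervention arm for
`intervention_cost_years` cycles, default 1: the published incremental
lifetime cost (~VND 1.9 million) is far below even one discounted
decade of VND 4 million/year, which is only consistent with a short
accrual window. The window is a config field and scenario analyses
should vary it.

## Decision rules

ICER verdicts are total over sign combinations: ratio (ΔC>0, ΔE>0),
dominant (ΔC≤0, ΔE>0), dominated (ΔC≥0, ΔE<0), south-west flagged
ratio (ΔC<0, ΔE<0), undefined (ΔE=0, never a division). PSA draws in
dominance quadrants are never converted to signed ICERs; the cloud and
the acceptability curve are the PSA summaries. The acceptability curve
uses the incremental net-monetary-benefit rule with strict inequality
(λ·ΔQALY − ΔC > 0; ties conservatively count as not cost-effective) on
a 0–300 million VND grid in 1-million steps with the 86.4 M and
259.2 M anchors guaranteed as grid points. Note the curve is provably
monotone in λ only over draws with ΔQALY ≥ 0; a cost-saving draw with a
QALY loss leaves the cost-effective set as λ grows, so a model whose
cloud straddles the ΔQALY axis can produce a locally decreasing curve.
This is a property of the rule, not a bug.

Reports round only at render time (VND to the dong, LY/QALY to two
decimals); all arithmetic uses full precision. Rendering differences of
*already-rounded* arm totals therefore reproduces published
incremental rows exactly, while full-precision increments may differ in
the last displayed digit.

## Synthetic data

Two study inputs are unpublished and replaced by documented synthetic
stand-ins, each a plug-in point for the real thing:

- **Life table**: Gompertz–Makeham hazards
  h(x) = A + B·e^(cx) per sex, ages 0–100, terminal qx = 1. Slope
  c = 0.1 and Makeham terms (0.0015 men, 0.0010 women) are typical
  adult values; baselines were tuned once
  (`synthetic.tune_gompertz_baseline`, manifest in
  `data/life_table_synthetic.yaml`) so curtate life expectancy at 50 is
  30.0 y (men) / 32.6 y (women) — inside the 30–33 y band the model's
  lifetime-LY scale implies for this population.
- **Risk equation**: a logistic 10-year first-event model in age, sex,
  SBP and smoking (coefficients in
  `data/risk_equation_synthetic.yaml`), monotone in all risk factors,
  centred to give ~8 % 10-year risk for a 50-year-old male hypertensive
  non-smoker. Cholesterol is deliberately absent, mirroring the study's
  data limitation.

Record-level generators emulate the study's data sources at their real
sizes: 15,533 outpatient + 2,553 inpatient billing records (per-record
Gamma, CV 0.8, strata allocated by the 1-central/1-provincial/
4-district hospital structure), 178 interviews (frequencies as
zero-truncated normals whose post-truncation means equal the truth —
the underlying location is solved for, keeping the sample mean
unbiased; utilities as moment-matched Betas per state/sex; non-medical
costs as Gammas), and 671 trial participants (individual SBP normal
with ~14 mmHg person-level SD, smoking Bernoulli, comparison-arm women
a structural zero). Person-level spreads are anchored to the published
standard errors scaled by the *study's* sample sizes, so estimating a
parameter table back from the synthetic records
(`estimate_parameters`: stratum mean + plain SEM, family assigned by
variable class) recovers the published table within sampling error.

What the synthetic stand-ins do **not** emulate: real Vietnamese
demography and case-mix, cost skew beyond a single-CV Gamma,
correlation between parameters, EQ-5D item structure, or the true risk
gradient. Passing tests therefore demonstrate that the *machinery* is
correct (probabilities valid, cohort = microsimulation, estimators
unbiased, decision rules exact), not that the defaults reproduce the
published cohort's numbers — that requires substituting the real life
table and risk equation at the plug-in points.

## Numerical choices

- Matrices validated row-stochastic to 1e-12; occupancy conservation
  asserted to 1e-10 over the lifetime.
- Hazard/probability conversions use `expm1`/`log1p`; the CVD death
  probability clamps the float round-trip so it is never below qx.
- The microsimulation oracle (inverse-CDF sampling on cumulative rows,
  vectorised over individuals) reports per-person means with
  Monte-Carlo SEs; agreement with the cohort engine is asserted within
  3 SEs at n = 50,000.
- Tornado entries sort by descending bar width with the parameter name
  as a deterministic tie-break; bars whose bound flips ΔQALY to zero
  are carried as NaN-width and sorted last rather than faked as ratios.
- PSA problem sizes: 10,000 draws for reported results, 5,000 per run
  for the two-seed stability check (curves agree to < 0.02 at every
  grid point at that size).

## Known limitations

- No tunnel states: event risk and costs do not depend on time since
  the event; acute-year costs apply to every recurrence year.
- MI and stroke are pooled into one acute state, as the source data
  pool the relevant ICD-10 codes.
- The comparison arm accrues no programme cost (routine care assumed
  costless beyond treatment encounters).
- Frequencies apply to all states sharing a setting; state-specific
  encounter frequencies were not published.
- Independence across PSA parameters overstates joint uncertainty
  where parameters are actually correlated (e.g. fees across levels).
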
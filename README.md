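# cohortcea

Lifetime cost-utility analysis of a community-based hypertension-control
programme, built as a reusable cohort Markov modelling package.

## The problem

Uncontrolled hypertension drives most cardiovascular disease (CVD) in
Vietnam. A multi-component community programme — expanded village
health-worker services, home blood-pressure self-monitoring and a
storytelling intervention — lowers systolic blood pressure (SBP) at
12 months, but policymakers need the *lifetime* trade-off: does the
programme's cost (about VND 4 million per person-year in its trial form,
~VND 430 thousand at national scale) buy enough avoided CVD events,
life-years (LY) and quality-adjusted life-years (QALYs) to be good value?

`cohortcea` answers that with a four-state cohort Markov model run from
age 50 over a lifetime horizon with 1-year cycles:

```
hypertension ──► acute CVD ──► stable CVD
      │              │  ▲  │        │
      ▼              ▼  └──┘        ▼
    death          death ◄────── death   (recurrence: stable ─► acute)
```

Per cycle, the hypertension-state hazard of a first acute event comes
from a pluggable k-year cardiovascular risk equation in age, sex, SBP
and smoking, annualised as `p₁ = 1 − (1 − p_k)^{1/k}`; background
mortality `qₓ` comes from a life table; CVD states add an excess death
rate on the hazard scale (`q = 1 − e^{−(−ln(1−qₓ) + r_excess)}`).
Recurrent events are assumed to carry the same annual probability as
first events. Each arm/sex cohort accrues costs (limited societal
perspective: medical fees plus patient-borne travel/meals/other), LYs
and utility-weighted QALYs, discounted at 3 %/year. Results:

- **Deterministic**: arm totals, ΔC, ΔE and the incremental
  cost-effectiveness ratio ICER = ΔC/ΔE;
- **One-way sensitivity**: tornado of the ICER over each parameter's
  95 % interval;
- **Probabilistic sensitivity analysis (PSA)**: 10,000 joint redraws of
  all uncertain parameters (Beta/Gamma/Normal, moment-matched to the
  published mean/SE), summarised on the cost-effectiveness plane and as
  an acceptability curve under the net-monetary-benefit rule
  `λ·ΔQALY − ΔC > 0`, with willingness-to-pay anchors at 1× and 3× the
  2021 GDP per capita (VND 86.4 / 259.2 million per QALY).

Two study inputs were never published: the national life table's `qx`
values and the Asian risk tool's coefficients. Both are **plug-in
points** (a life-table CSV and a risk-equation manifest/contract); the
package ships clearly-labelled synthetic stand-ins (a Gompertz–Makeham
life table and a logistic risk equation), so every number computed with
the defaults characterises the *method*, not the published cohort.

## Worked example

```python
from cohortcea import *
from cohortcea.synthetic import make_life_table

specs = load_default_parameters()          # the 38-row parameter table
means = parameter_means(specs)
lt, eq, cfg = make_life_table(), default_risk_equation(), ModelConfig()

det = run_deterministic(means, lt, eq, cfg)
print(deterministic_table(det).to_string(index=False))

psa = run_psa(specs, lt, eq, cfg, n_draws=2000, seed=7)
curve = ceac(psa)
print(f"P(cost-effective) at 1 GDP/QALY: {curve.at(86_400_000):.3f}")
print(f"P(cost-effective) at 3 GDP/QALY: {curve.at(259_200_000):.3f}")
```

prints (with the synthetic stand-in life table and risk equation):

```
                     Comparison Intervention
          Cost (VND)  163793055    160490101
                 LYs       19.2        19.22
               QALYs      13.83        13.88
    Incremental cost                -3302954
      Incremental LY                    0.02
    Incremental QALY                    0.05
    ICER/LY (VND/LY)                dominant
ICER/QALY (VND/QALY)                dominant

P(cost-effective) at 1 GDP/QALY: 0.971
P(cost-effective) at 3 GDP/QALY: 0.937
```

Reading: under the stand-ins, the intervention arm's lower SBP avoids
enough costly acute admissions that the programme *saves* ~VND 3.3
million per person over a lifetime while gaining 0.05 discounted QALYs —
it dominates routine care, and ~97 % of PSA draws are cost-effective at
the 1-GDP threshold. (Costs and LY/QALY rows here are discounted at 3 %;
`deterministic_table(det, discounted=False)` renders the undiscounted
convention.) Substituting the true national life table and risk-tool
coefficients via the plug-in points is required to reproduce the
published cohort's results.

The same analysis is available from a shell:

```bash
cohortcea --params src/cohortcea/data/table1_params.csv \
          --mode psa --draws 10000 --seed 1 --out results/
```

## Layout

| module | contents |
|---|---|
| `cohortcea.params` | parameter table, moment-matched Beta/Gamma/Normal specs, 95 % ranges, joint sampling |
| `cohortcea.risk` | risk-equation contract + logistic stand-in, annualisation, life table, CVD excess mortality |
| `cohortcea.markov` | four-state transition matrices, cohort engine, microsimulation oracle |
| `cohortcea.costing` | encounter costs, per-state annual costs, programme-cost modes |
| `cohortcea.model` | wiring from a parameter set to full arm runs |
| `cohortcea.analysis` | deterministic ICERs, tornado, PSA, CEAC, CE plane |
| `cohortcea.synthetic` | synthetic life table, billing/interview/trial generators, parameter estimator |
| `cohortcea.report`, `cohortcea.plots`, `cohortcea.cli` | rendering, figures, command line |

See `docs/methods.md` for the model's assumptions, parameter
conventions, and known limitations.
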
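"""Wiring from a named parameter set to full lifetime arm runs.

Covariates (SBP, cohort smoking prevalence) are frozen at their
12-month trial values per arm and sex while age advances cycle by
cycle; an optional effect-waning half-life decays the intervention arm's
covariates toward the comparison arm's.  Each cycle's transition matrix
combines the annualized acute-event risk, the life-table background
death probability, and the hazard-scale CVD mortality escalation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .costing import annual_state_cost, cost_inputs_from_values
from .markov import (
    ARMS,
    COMPARISON,
    INTERVENTION,
    N_STATES,
    CohortTrace,
    HealthState,
    ModelConfig,
    RunTotals,
    aggregate_sexes,
    run_cohort,
    run_microsim,
)
from .risk import (
    FEMALE,
    MALE,
    CvdExcessMortality,
    LifeTable,
    RiskEquation,
)

_ARM_TAG = {INTERVENTION: "int", COMPARISON: "com"}


def excess_mortality_from_values(values) -> CvdExcessMortality:
    return CvdExcessMortality(male=values["mort_cvd_m"], female=values["mort_cvd_f"])


def arm_covariates(values, arm: str, sex: str, cycles: np.ndarray,
                   config: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle (SBP, smoking prevalence) for one arm and sex.

    ``cycles`` are 0-based cycle indices.  With a finite waning
    half-life the intervention arm's covariates decay geometrically
    toward the comparison arm's values; the default (infinite) keeps the
    12-month effect for life.
    """
    tag = "m" if sex == MALE else "f"
    sbp_com = values[f"sbp_com_{tag}"]
    smoke_com = values[f"smoke_com_{tag}"]
    if arm == COMPARISON:
        ones = np.ones_like(cycles, dtype=float)
        return sbp_com * ones, smoke_com * ones
    sbp_int = values[f"sbp_int_{tag}"]
    smoke_int = values[f"smoke_int_{tag}"]
    if np.isinf(config.effect_waning_half_life):
        persist = np.ones_like(cycles, dtype=float)
    else:
        persist = 0.5 ** (np.asarray(cycles, dtype=float)
                          / config.effect_waning_half_life)
    return (sbp_com + (sbp_int - sbp_com) * persist,
            smoke_com + (smoke_int - smoke_com) * persist)


def build_matrices(values, arm: str, sex: str, lt: LifeTable,
                   eq: RiskEquation, config: ModelConfig) -> np.ndarray:
    """Stack of (n_cycles, 4, 4) transition matrices for one arm and sex."""
    n = config.n_cycles
    ages = config.start_age + np.arange(n)
    cycles = np.arange(n)
    sbp, smoking = arm_covariates(values, arm, sex, cycles, config)
    k = eq.horizon_years
    p_smoker = np.asarray(eq.k_year_risk(ages, sex, sbp, 1.0), dtype=float)
    p_nonsmoker = np.asarray(eq.k_year_risk(ages, sex, sbp, 0.0), dtype=float)
    a_smoker = 1.0 - (1.0 - p_smoker) ** (1.0 / k)
    a_nonsmoker = 1.0 - (1.0 - p_nonsmoker) ** (1.0 / k)
    p_acute = smoking * a_smoker + (1.0 - smoking) * a_nonsmoker
    qx = lt.qx_slice(ages, sex)
    excess = excess_mortality_from_values(values).rate(sex)
    with np.errstate(divide="ignore"):
        q_cvd = np.where(
            qx >= 1.0, 1.0, -np.expm1(-(-np.log1p(-np.minimum(qx, 1 - 1e-15))
                                        + excess)),
        )
    q_cvd = np.minimum(q_cvd, 1.0)
    m = np.zeros((n, N_STATES, N_STATES))
    acute_from_htn = p_acute * (1.0 - qx)
    m[:, HealthState.HTN, HealthState.DEAD] = qx
    m[:, HealthState.HTN, HealthState.ACUTE_CVD] = acute_from_htn
    m[:, HealthState.HTN, HealthState.HTN] = 1.0 - qx - acute_from_htn
    recur = p_acute * (1.0 - q_cvd)
    m[:, HealthState.ACUTE_CVD, HealthState.DEAD] = q_cvd
    m[:, HealthState.ACUTE_CVD, HealthState.ACUTE_CVD] = recur
    m[:, HealthState.ACUTE_CVD, HealthState.STABLE_CVD] = 1.0 - q_cvd - recur
    m[:, HealthState.STABLE_CVD, HealthState.DEAD] = q_cvd
    m[:, HealthState.STABLE_CVD, HealthState.ACUTE_CVD] = recur
    m[:, HealthState.STABLE_CVD, HealthState.STABLE_CVD] = 1.0 - q_cvd - recur
    m[:, HealthState.DEAD, HealthState.DEAD] = 1.0
    return m


def build_rewards(values, arm: str, sex: str,
                  config: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle (costs, utilities) arrays of shape (n_cycles, 4).

    The programme cost enters the hypertension-state cost of the
    intervention arm for the first ``intervention_cost_years`` cycles.
    """
    n = config.n_cycles
    tag = "m" if sex == MALE else "f"
    freq, unit_costs, non_medical, ic = cost_inputs_from_values(
        values, mode=config.intervention_mode
    )
    base = np.zeros(N_STATES)
    windowed = np.zeros(N_STATES)
    for state in (HealthState.HTN, HealthState.ACUTE_CVD, HealthState.STABLE_CVD):
        base[state] = annual_state_cost(
            state, arm, freq, unit_costs, non_medical, ic, in_window=False
        )
        windowed[state] = annual_state_cost(
            state, arm, freq, unit_costs, non_medical, ic, in_window=True
        )
    costs = np.tile(base, (n, 1))
    w = min(config.intervention_cost_years, n)
    costs[:w] = windowed
    utilities = np.zeros(N_STATES)
    utilities[HealthState.HTN] = values[f"u_htn_{tag}"]
    utilities[HealthState.ACUTE_CVD] = values[f"u_acute_{tag}"]
    utilities[HealthState.STABLE_CVD] = values[f"u_stable_{tag}"]
    return costs, np.tile(utilities, (n, 1))


def run_arm_sex(values, arm: str, sex: str, lt: LifeTable, eq: RiskEquation,
                config: ModelConfig) -> CohortTrace:
    """Full lifetime cohort run for one (arm, sex) stratum."""
    matrices = build_matrices(values, arm, sex, lt, eq, config)
    costs, utilities = build_rewards(values, arm, sex, config)
    return run_cohort(config, matrices, costs, utilities)


def run_arm(values, arm: str, lt: LifeTable, eq: RiskEquation,
            config: ModelConfig) -> RunTotals:
    """Sex-weighted lifetime totals for one arm."""
    male = run_arm_sex(values, arm, MALE, lt, eq, config).totals
    female = run_arm_sex(values, arm, FEMALE, lt, eq, config).totals
    return aggregate_sexes(male, female, config.sex_weights)


def run_both_arms(values, lt: LifeTable, eq: RiskEquation,
                  config: ModelConfig) -> dict[str, RunTotals]:
    return {arm: run_arm(values, arm, lt, eq, config) for arm in ARMS}


@dataclass(frozen=True)
class MicrosimArm:
    totals: RunTotals
    se: RunTotals
    n: int


def run_arm_microsim(values, arm: str, lt: LifeTable, eq: RiskEquation,
                     config: ModelConfig, n: int,
                     rng: np.random.Generator) -> MicrosimArm:
    """Microsimulation oracle for one arm, sexes pooled by assignment.

    Individuals are assigned a sex by the configured weights, then
    walked through that sex's matrices; totals/SEs are per person.
    """
    n_male = int(round(n * config.sex_weights[0]))
    parts = []
    for sex, n_sex in ((MALE, n_male), (FEMALE, n - n_male)):
        if n_sex == 0:
            continue
        matrices = build_matrices(values, arm, sex, lt, eq, config)
        costs, utilities = build_rewards(values, arm, sex, config)
        parts.append(run_microsim(config, matrices, costs, utilities, n_sex, rng))
    if len(parts) == 1:
        r = parts[0]
        return MicrosimArm(r.totals, r.se, r.n)
    w = np.array([p.n for p in parts], dtype=float)
    w /= w.sum()
    totals = parts[0].totals.scaled(w[0]) + parts[1].totals.scaled(w[1])
    se = RunTotals(*np.sqrt(sum(
        (wi * np.array(p.se._tuple())) ** 2 for wi, p in zip(w, parts)
    )))
    return MicrosimArm(totals, se, n)
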
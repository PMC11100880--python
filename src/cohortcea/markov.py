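"""Cohort Markov engine over the four-state hypertension topology.

States: hypertension (HTN) -> acute CVD -> stable CVD -> dead, with
recurrence from both CVD states and death reachable from every live
state; DEAD is absorbing.  The cohort starts fully in HTN at the start
age and is propagated one 1-year cycle at a time through age-specific
row-stochastic matrices, accruing costs, life-years and QALYs (both
discounted and undiscounted).  A microsimulation over the same matrices
serves as an independent verification oracle.

Competing risks within a row: the death probability is computed first,
the acute-event probability is scaled by (1 - death), and the residual
mass goes to the stay/stable destination — rows are valid by
construction, with no truncation beyond the hazard-scale cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .params import DiscountRates, ParameterSet
from .risk import (
    CvdExcessMortality,
    LifeTable,
    RiskEquation,
    RiskProfile,
    annual_acute_cvd_prob,
    cvd_state_death_prob,
)

logger = logging.getLogger(__name__)

INTERVENTION = "intervention"
COMPARISON = "comparison"
ARMS = (INTERVENTION, COMPARISON)


class HealthState(IntEnum):
    HTN = 0
    ACUTE_CVD = 1
    STABLE_CVD = 2
    DEAD = 3


N_STATES = len(HealthState)

#: (from, to) pairs that the topology forbids.
STRUCTURAL_ZEROS = (
    (HealthState.HTN, HealthState.STABLE_CVD),
    (HealthState.STABLE_CVD, HealthState.HTN),
    (HealthState.ACUTE_CVD, HealthState.HTN),
    (HealthState.DEAD, HealthState.HTN),
    (HealthState.DEAD, HealthState.ACUTE_CVD),
    (HealthState.DEAD, HealthState.STABLE_CVD),
)


@dataclass(frozen=True)
class ModelConfig:
    """Run-level configuration of the lifetime cohort model."""

    start_age: int = 50
    terminal_age: int = 100
    cycle_years: float = 1.0
    discounts: DiscountRates = field(default_factory=DiscountRates)
    half_cycle_correction: bool = False
    intervention_cost_years: int = 1
    sex_weights: tuple[float, float] = (0.5, 0.5)  # (male, female)
    effect_waning_half_life: float = np.inf  # years; inf = effect persists
    intervention_mode: str = "trial"  # or "scale_up"

    def __post_init__(self) -> None:
        if self.start_age >= self.terminal_age:
            raise ValueError("start_age must be below terminal_age")
        if abs(sum(self.sex_weights) - 1.0) > 1e-9:
            raise ValueError("sex_weights must sum to 1")
        if self.intervention_cost_years < 0:
            raise ValueError("intervention_cost_years must be >= 0")

    @property
    def n_cycles(self) -> int:
        """Cycles cover ages start..terminal inclusive, so the final cycle
        applies the terminal age's qx = 1 and empties the live states."""
        return self.terminal_age - self.start_age + 1


def transition_matrix_from_probs(
    p_acute: float, q_death_htn: float, q_death_cvd: float
) -> np.ndarray:
    """Assemble one 4x4 row-stochastic matrix from annual probabilities.

    ``p_acute`` is the annual acute-event probability (used for first
    events and, by assumption, recurrences), ``q_death_htn`` the
    background death probability, ``q_death_cvd`` the elevated death
    probability in CVD states.
    """
    for name, p in (("p_acute", p_acute), ("q_death_htn", q_death_htn),
                    ("q_death_cvd", q_death_cvd)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]; got {p}")
    m = np.zeros((N_STATES, N_STATES))
    # HTN row: death first, acute scaled by survival, residual stays.
    acute_from_htn = p_acute * (1.0 - q_death_htn)
    m[HealthState.HTN, HealthState.DEAD] = q_death_htn
    m[HealthState.HTN, HealthState.ACUTE_CVD] = acute_from_htn
    m[HealthState.HTN, HealthState.HTN] = 1.0 - q_death_htn - acute_from_htn
    # ACUTE row: recurrence keeps the patient in ACUTE; residual moves to STABLE.
    recur = p_acute * (1.0 - q_death_cvd)
    m[HealthState.ACUTE_CVD, HealthState.DEAD] = q_death_cvd
    m[HealthState.ACUTE_CVD, HealthState.ACUTE_CVD] = recur
    m[HealthState.ACUTE_CVD, HealthState.STABLE_CVD] = 1.0 - q_death_cvd - recur
    # STABLE row: recurrence sends the patient back to ACUTE; residual stays.
    m[HealthState.STABLE_CVD, HealthState.DEAD] = q_death_cvd
    m[HealthState.STABLE_CVD, HealthState.ACUTE_CVD] = recur
    m[HealthState.STABLE_CVD, HealthState.STABLE_CVD] = 1.0 - q_death_cvd - recur
    m[HealthState.DEAD, HealthState.DEAD] = 1.0
    if np.any(m < -1e-12):
        raise ValueError("negative residual probability after renormalization")
    np.clip(m, 0.0, 1.0, out=m)
    return m


def build_transition_matrix(
    age: int,
    sex: str,
    arm_params: ParameterSet | dict,
    eq: RiskEquation,
    lt: LifeTable,
    excess: CvdExcessMortality,
    *,
    sbp: float | None = None,
    smoking: float | None = None,
) -> np.ndarray:
    """Age/sex/arm-specific transition matrix.

    Covariates may be given directly (``sbp``/``smoking``) or read from
    ``arm_params`` under the keys ``sbp`` and ``smoking``.
    """
    if sbp is None:
        sbp = arm_params["sbp"]
    if smoking is None:
        smoking = arm_params["smoking"]
    profile = RiskProfile(age=age, sex=sex, sbp=sbp, smoking=smoking)
    p_acute = annual_acute_cvd_prob(profile, eq)
    qx = lt.qx(age, sex)
    q_cvd = cvd_state_death_prob(qx, excess, sex)
    return transition_matrix_from_probs(p_acute, qx, q_cvd)


def validate_matrix(m: np.ndarray, atol: float = 1e-12) -> None:
    """Raise if ``m`` is not row-stochastic or violates the topology."""
    if m.shape != (N_STATES, N_STATES):
        raise ValueError(f"expected {N_STATES}x{N_STATES} matrix; got {m.shape}")
    if np.any(m < -atol):
        raise ValueError("negative transition probability")
    if not np.allclose(m.sum(axis=1), 1.0, atol=atol):
        raise ValueError("rows must sum to 1")
    for i, j in STRUCTURAL_ZEROS:
        if m[i, j] > atol:
            raise ValueError(f"structural zero violated: {i.name}->{j.name}")


@dataclass(frozen=True)
class RunTotals:
    """Lifetime per-person totals from a cohort or microsimulation run."""

    cost: float
    ly: float
    qaly: float
    cost_disc: float
    ly_disc: float
    qaly_disc: float

    def __add__(self, other: "RunTotals") -> "RunTotals":
        return RunTotals(*(a + b for a, b in zip(self._tuple(), other._tuple())))

    def scaled(self, w: float) -> "RunTotals":
        return RunTotals(*(w * a for a in self._tuple()))

    def _tuple(self) -> tuple[float, ...]:
        return (self.cost, self.ly, self.qaly,
                self.cost_disc, self.ly_disc, self.qaly_disc)


@dataclass
class CohortTrace:
    """Per-cycle occupancy and reward streams of one cohort run.

    ``occupancy[t]`` is the state distribution *after* the t-th
    transition (t = 1..n_cycles); row 0 is the initial distribution.
    """

    start_age: int
    occupancy: np.ndarray          # (n_cycles+1, 4)
    cost: np.ndarray               # (n_cycles,) undiscounted per cycle
    ly: np.ndarray
    qaly: np.ndarray
    cost_disc: np.ndarray
    ly_disc: np.ndarray
    qaly_disc: np.ndarray

    @property
    def totals(self) -> RunTotals:
        return RunTotals(
            cost=float(self.cost.sum()), ly=float(self.ly.sum()),
            qaly=float(self.qaly.sum()),
            cost_disc=float(self.cost_disc.sum()),
            ly_disc=float(self.ly_disc.sum()),
            qaly_disc=float(self.qaly_disc.sum()),
        )

    def to_frame(self) -> pd.DataFrame:
        n = len(self.cost)
        return pd.DataFrame({
            "cycle": np.arange(1, n + 1),
            "age": self.start_age + np.arange(1, n + 1),
            "occ_htn": self.occupancy[1:, HealthState.HTN],
            "occ_acute": self.occupancy[1:, HealthState.ACUTE_CVD],
            "occ_stable": self.occupancy[1:, HealthState.STABLE_CVD],
            "occ_dead": self.occupancy[1:, HealthState.DEAD],
            "cost": self.cost, "qaly": self.qaly, "ly": self.ly,
            "cost_disc": self.cost_disc, "qaly_disc": self.qaly_disc,
            "ly_disc": self.ly_disc,
        })


def _reward_arrays(matrices, costs, utilities):
    n = len(matrices)
    costs = np.asarray(costs, dtype=float)
    if costs.ndim == 1:
        costs = np.broadcast_to(costs, (n, N_STATES))
    utilities = np.asarray(utilities, dtype=float)
    if utilities.ndim == 1:
        utilities = np.broadcast_to(utilities, (n, N_STATES))
    if costs.shape != (n, N_STATES) or utilities.shape != (n, N_STATES):
        raise ValueError("reward arrays must have shape (n_cycles, 4) or (4,)")
    return costs, utilities


def run_cohort(
    config: ModelConfig,
    matrices: np.ndarray,
    costs: np.ndarray,
    utilities: np.ndarray,
    start: np.ndarray | None = None,
) -> CohortTrace:
    """Propagate the cohort and accrue rewards end-of-cycle.

    ``matrices`` has shape (n_cycles, 4, 4): one matrix per model age.
    ``costs``/``utilities`` give per-state annual rewards, either one
    row per cycle or a single row applied throughout.  Cycle t's reward
    is the post-transition occupancy dotted with the per-state reward,
    discounted by (1+r)^-t; with half-cycle correction the mean of the
    pre- and post-transition occupancies is used instead.
    """
    matrices = np.asarray(matrices, dtype=float)
    n = config.n_cycles
    if matrices.shape != (n, N_STATES, N_STATES):
        raise ValueError(
            f"need one matrix per age in [{config.start_age}, "
            f"{config.terminal_age}]; got shape {matrices.shape}"
        )
    costs, utilities = _reward_arrays(matrices, costs, utilities)
    occ = np.zeros((n + 1, N_STATES))
    occ[0] = (np.array([1.0, 0.0, 0.0, 0.0]) if start is None
              else np.asarray(start, dtype=float))
    alive = np.array([1.0, 1.0, 1.0, 0.0])
    t_idx = np.arange(1, n + 1)
    disc_c = (1.0 + config.discounts.cost_rate) ** -t_idx
    disc_e = (1.0 + config.discounts.effect_rate) ** -t_idx
    for t in range(n):
        occ[t + 1] = occ[t] @ matrices[t]
    weight = 0.5 * (occ[:-1] + occ[1:]) if config.half_cycle_correction else occ[1:]
    cost = np.einsum("ts,ts->t", weight, costs)
    ly = weight @ alive
    qaly = np.einsum("ts,ts->t", weight, utilities)
    return CohortTrace(
        start_age=config.start_age, occupancy=occ,
        cost=cost, ly=ly, qaly=qaly,
        cost_disc=cost * disc_c, ly_disc=ly * disc_e, qaly_disc=qaly * disc_e,
    )


@dataclass(frozen=True)
class MicrosimResult:
    totals: RunTotals
    se: RunTotals
    n: int


def run_microsim(
    config: ModelConfig,
    matrices: np.ndarray,
    costs: np.ndarray,
    utilities: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> MicrosimResult:
    """Individual-level walk through the same matrices (verification oracle).

    Simulates ``n`` independent trajectories; smoking enters these
    matrices as prevalence already, so individuals differ only through
    transition randomness.  Returns per-person mean totals and their
    Monte-Carlo standard errors.
    """
    if n < 1:
        raise ValueError("need at least one simulated individual")
    matrices = np.asarray(matrices, dtype=float)
    n_cycles = config.n_cycles
    costs, utilities = _reward_arrays(matrices, costs, utilities)
    cum = np.cumsum(matrices, axis=2)
    state = np.zeros(n, dtype=np.intp)  # everyone starts in HTN
    acc = np.zeros((n, 6))  # cost, ly, qaly, cost_disc, ly_disc, qaly_disc
    t_idx = np.arange(1, n_cycles + 1)
    disc_c = (1.0 + config.discounts.cost_rate) ** -t_idx
    disc_e = (1.0 + config.discounts.effect_rate) ** -t_idx
    for t in range(n_cycles):
        u = rng.random(n)
        state_prev = state
        state = (u[:, None] > cum[t][state_prev]).sum(axis=1)
        if config.half_cycle_correction:
            alive = 0.5 * ((state_prev != HealthState.DEAD)
                           + (state != HealthState.DEAD))
            c = 0.5 * (costs[t][state_prev] + costs[t][state])
            q = 0.5 * (utilities[t][state_prev] + utilities[t][state])
            # dead contributes nothing (reward rows for DEAD are zero)
        else:
            alive = (state != HealthState.DEAD).astype(float)
            c = costs[t][state]
            q = utilities[t][state]
        acc[:, 0] += c
        acc[:, 1] += alive
        acc[:, 2] += q
        acc[:, 3] += c * disc_c[t]
        acc[:, 4] += alive * disc_e[t]
        acc[:, 5] += q * disc_e[t]
    mean = acc.mean(axis=0)
    se = acc.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(6)
    return MicrosimResult(RunTotals(*mean), RunTotals(*se), n)


def aggregate_sexes(
    result_male: RunTotals, result_female: RunTotals, weights: tuple[float, float]
) -> RunTotals:
    """Sex-weighted convex combination of per-person totals."""
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("sex weights must sum to 1")
    return result_male.scaled(weights[0]) + result_female.scaled(weights[1])
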
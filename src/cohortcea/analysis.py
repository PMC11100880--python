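"""Economic result layers: deterministic ICERs, tornado, and PSA.

The deterministic layer runs both arms at parameter means and reports
incremental cost, life-years and QALYs with the resulting ICERs.  The
one-way layer reruns the deterministic model at each parameter's 95%
bounds (tornado).  The probabilistic layer redraws every uncertain
parameter jointly (independently across parameters, arm-specific where
the parameter table defines them per arm) for each of n draws, and
summarises the (dCost, dQALY) cloud on the cost-effectiveness plane and
as an acceptability curve under the incremental net-monetary-benefit
rule: cost-effective at willingness-to-pay lambda iff
lambda*dQALY - dCost > 0 (ties count as not cost-effective).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .markov import COMPARISON, INTERVENTION, ModelConfig, RunTotals
from .model import run_both_arms
from .params import (
    MODEL_PARAMETER_NAMES,
    ParameterSet,
    ParameterSpec,
    ci95,
    parameter_means,
    sample_parameter,
)
from .risk import LifeTable, RiskEquation


@dataclass(frozen=True)
class WtpThresholds:
    """Willingness-to-pay anchors: 1x and 3x 2021 GDP per capita (VND/QALY)."""

    gdp1: float = 86_400_000.0
    gdp3: float = 3 * 86_400_000.0


class Verdict(Enum):
    RATIO = "ratio"              # more costly, more effective: report ICER
    DOMINANT = "dominant"        # cheaper and at least as effective
    DOMINATED = "dominated"      # costlier and less effective
    SOUTHWEST = "southwest"      # cheaper and less effective: ratio + flag
    UNDEFINED = "undefined"      # zero effect difference


@dataclass(frozen=True)
class IcerResult:
    verdict: Verdict
    value: float | None  # VND per unit effect where a ratio is meaningful


def icer(delta_cost: float, delta_effect: float) -> IcerResult:
    """Map an incremental (cost, effect) pair to an ICER verdict.

    Every sign combination has exactly one verdict; a zero effect
    difference is 'undefined' and never divided through.
    """
    if delta_effect == 0:
        return IcerResult(Verdict.UNDEFINED, None)
    if delta_effect > 0:
        if delta_cost > 0:
            return IcerResult(Verdict.RATIO, delta_cost / delta_effect)
        return IcerResult(Verdict.DOMINANT, None)
    if delta_cost >= 0:
        return IcerResult(Verdict.DOMINATED, None)
    return IcerResult(Verdict.SOUTHWEST, delta_cost / delta_effect)


@dataclass(frozen=True)
class DeterministicResult:
    """Both arms' lifetime totals and the incremental comparison.

    Deltas and ICERs use the discounted streams (the base case discounts
    both costs and effects); undiscounted totals are carried alongside.
    """

    intervention: RunTotals
    comparison: RunTotals

    @property
    def delta_cost(self) -> float:
        return self.intervention.cost_disc - self.comparison.cost_disc

    @property
    def delta_ly(self) -> float:
        return self.intervention.ly_disc - self.comparison.ly_disc

    @property
    def delta_qaly(self) -> float:
        return self.intervention.qaly_disc - self.comparison.qaly_disc

    @property
    def icer_per_ly(self) -> IcerResult:
        return icer(self.delta_cost, self.delta_ly)

    @property
    def icer_per_qaly(self) -> IcerResult:
        return icer(self.delta_cost, self.delta_qaly)


def _require_complete(values: ParameterSet) -> None:
    missing = values.missing(MODEL_PARAMETER_NAMES)
    if missing:
        raise ValueError("incomplete parameter set; missing: " + ", ".join(missing))


def run_deterministic(
    values: ParameterSet,
    lt: LifeTable,
    eq: RiskEquation,
    config: ModelConfig,
) -> DeterministicResult:
    """Both arms at the given (usually mean) parameter values."""
    _require_complete(values)
    totals = run_both_arms(values, lt, eq, config)
    return DeterministicResult(
        intervention=totals[INTERVENTION], comparison=totals[COMPARISON]
    )


@dataclass(frozen=True)
class TornadoEntry:
    name: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def width(self) -> float:
        if math.isnan(self.icer_low) or math.isnan(self.icer_high):
            return math.nan
        return abs(self.icer_high - self.icer_low)


def _signed_icer_per_qaly(res: DeterministicResult) -> float:
    """Signed dC/dQALY for tornado bars; NaN when the QALY delta is zero."""
    if res.delta_qaly == 0:
        return math.nan
    return res.delta_cost / res.delta_qaly


def one_way_sensitivity(
    specs: Sequence[ParameterSpec],
    lt: LifeTable,
    eq: RiskEquation,
    config: ModelConfig,
) -> list[TornadoEntry]:
    """One-way (tornado) sensitivity of the ICER per QALY.

    Each non-fixed parameter is set to its 95% bounds in turn with all
    others held at their means; entries come back sorted by descending
    bar width, name as tie-break.  A non-fixed parameter with a
    degenerate SE of zero yields a zero-width bar; fixed-family
    parameters are excluded.
    """
    means = parameter_means(specs)
    _require_complete(means)
    varying = [s for s in specs if s.family != "fixed"]
    if not varying:
        warnings.warn("no non-fixed parameters; tornado is empty")
        return []
    entries = []
    for spec in varying:
        low, high = ci95(spec)
        icers = []
        for bound in (low, high):
            vals = dict(means.values)
            vals[spec.name] = bound
            res = run_deterministic(
                ParameterSet(vals, provenance=f"oneway({spec.name})"),
                lt, eq, config,
            )
            icers.append(_signed_icer_per_qaly(res))
        entries.append(TornadoEntry(spec.name, low, high, icers[0], icers[1]))
    return sorted(entries, key=lambda e: (-(e.width if not math.isnan(e.width)
                                            else -math.inf), e.name))


def tornado_frame(entries: Iterable[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.name, e.low, e.high, e.icer_low, e.icer_high, e.width)
         for e in entries],
        columns=["name", "low", "high", "icer_low", "icer_high", "width"],
    )


def sample_parameter_set(
    specs: Sequence[ParameterSpec], rng: np.random.Generator, label: str
) -> ParameterSet:
    """One joint draw: every non-fixed parameter sampled independently."""
    return ParameterSet(
        {s.name: sample_parameter(s, rng) for s in specs}, provenance=label
    )


def run_psa(
    specs: Sequence[ParameterSpec],
    lt: LifeTable,
    eq: RiskEquation,
    config: ModelConfig,
    n_draws: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Probabilistic sensitivity analysis.

    Each draw jointly resamples all uncertain parameters (arm-specific
    parameters are separate table entries and so are drawn per arm),
    runs both arms, and records the incremental discounted cost, QALYs
    and LYs.  Draw i is reproducible from (seed, i) via spawned child
    seeds.  Returns a frame with columns ``draw, dcost, dqaly, dly``.
    """
    if n_draws < 1:
        raise ValueError("need at least one draw")
    means = parameter_means(specs)
    _require_complete(means)
    children = np.random.SeedSequence(seed).spawn(n_draws)
    rows = np.empty((n_draws, 3))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        values = sample_parameter_set(specs, rng, f"psa_draw(seed={seed}, index={i})")
        totals = run_both_arms(values, lt, eq, config)
        d = DeterministicResult(totals[INTERVENTION], totals[COMPARISON])
        rows[i] = (d.delta_cost, d.delta_qaly, d.delta_ly)
    return pd.DataFrame(rows, columns=["dcost", "dqaly", "dly"]).assign(
        draw=np.arange(n_draws)
    )[["draw", "dcost", "dqaly", "dly"]]


def default_wtp_grid(
    stop: float = 300e6, step: float = 1e6,
    thresholds: WtpThresholds = WtpThresholds(),
) -> np.ndarray:
    """0..300 million VND/QALY in 1-million steps, with the GDP anchors
    guaranteed to be grid points."""
    grid = np.arange(0.0, stop + step / 2, step)
    grid = np.union1d(grid, [thresholds.gdp1, thresholds.gdp3])
    return grid


@dataclass(frozen=True)
class Ceac:
    wtp: np.ndarray
    probability: np.ndarray

    def at(self, wtp: float) -> float:
        idx = np.nonzero(np.isclose(self.wtp, wtp))[0]
        if idx.size == 0:
            raise KeyError(f"willingness-to-pay {wtp} not on the grid")
        return float(self.probability[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


def ceac(draws: pd.DataFrame, wtp_grid: np.ndarray | None = None) -> Ceac:
    """Probability cost-effective vs willingness-to-pay.

    Incremental net-monetary-benefit rule with strict inequality:
    a draw counts as cost-effective at lambda iff
    lambda*dQALY - dCost > 0.
    """
    if len(draws) == 0:
        raise ValueError("need at least one draw")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    if grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("willingness-to-pay grid must be strictly increasing")
    dq = draws["dqaly"].to_numpy()
    dc = draws["dcost"].to_numpy()
    nmb = grid[:, None] * dq[None, :] - dc[None, :]
    prob = (nmb > 0).mean(axis=1)
    return Ceac(grid, prob)


@dataclass(frozen=True)
class CePlaneSummary:
    """Quadrant occupancy of the incremental cloud plus its mean point.

    Boundary convention: draws on an axis count toward the positive
    side, so the four fractions always sum to 1.
    """

    ne: float  # dQALY >= 0, dCost >= 0
    nw: float  # dQALY <  0, dCost >= 0
    se: float  # dQALY >= 0, dCost <  0
    sw: float  # dQALY <  0, dCost <  0
    mean_dcost: float
    mean_dqaly: float


def ce_plane_summary(draws: pd.DataFrame) -> CePlaneSummary:
    if len(draws) == 0:
        raise ValueError("need at least one draw")
    dq = draws["dqaly"].to_numpy()
    dc = draws["dcost"].to_numpy()
    east, north = dq >= 0, dc >= 0
    return CePlaneSummary(
        ne=float((east & north).mean()),
        nw=float((~east & north).mean()),
        se=float((east & ~north).mean()),
        sw=float((~east & ~north).mean()),
        mean_dcost=float(dc.mean()),
        mean_dqaly=float(dq.mean()),
    )
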
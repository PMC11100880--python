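"""Result rendering in the deterministic-analysis table layout.

All arithmetic happens at full precision; rounding (costs to the dong,
life-years and QALYs to two decimals) is applied only when a table is
rendered.  :func:`incremental_summary` also accepts already-rounded
published arm totals and reproduces their printed differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .analysis import DeterministicResult, Verdict


@dataclass(frozen=True)
class ArmTotals:
    """Arm-level lifetime totals as they appear in a results table."""

    cost: float
    ly: float
    qaly: float


def incremental_summary(
    comparison: ArmTotals, intervention: ArmTotals
) -> pd.DataFrame:
    """Render the incremental rows from two arms' (possibly rounded) totals.

    Differences are taken on the supplied values and only then rounded
    for display, so printed arm totals reproduce printed increments.
    """
    d_cost = intervention.cost - comparison.cost
    d_ly = intervention.ly - comparison.ly
    d_qaly = intervention.qaly - comparison.qaly
    rows = [
        ("Cost (VND)", round(comparison.cost), round(intervention.cost)),
        ("LYs", round(comparison.ly, 2), round(intervention.ly, 2)),
        ("QALYs", round(comparison.qaly, 2), round(intervention.qaly, 2)),
        ("Incremental cost", "", round(d_cost)),
        ("Incremental LY", "", round(d_ly, 2)),
        ("Incremental QALY", "", round(d_qaly, 2)),
    ]
    if d_ly > 0 and d_cost > 0:
        rows.append(("ICER/LY (VND/LY)", "", round(d_cost / d_ly)))
    if d_qaly > 0 and d_cost > 0:
        rows.append(("ICER/QALY (VND/QALY)", "", round(d_cost / d_qaly)))
    return pd.DataFrame(rows, columns=["", "Comparison", "Intervention"])


def _icer_cell(res) -> object:
    if res.verdict == Verdict.RATIO:
        return round(res.value)
    if res.verdict == Verdict.SOUTHWEST:
        return f"{round(res.value)} (south-west)"
    return res.verdict.value


def deterministic_table(
    result: DeterministicResult, discounted: bool = True
) -> pd.DataFrame:
    """Full deterministic-analysis table from a model run.

    Deltas and ICERs are computed at full precision before render-time
    rounding (so the displayed increments may differ in the last digit
    from differences of the displayed arm totals).
    """
    com, inter = result.comparison, result.intervention
    if discounted:
        c = ArmTotals(com.cost_disc, com.ly_disc, com.qaly_disc)
        i = ArmTotals(inter.cost_disc, inter.ly_disc, inter.qaly_disc)
    else:
        c = ArmTotals(com.cost, com.ly, com.qaly)
        i = ArmTotals(inter.cost, inter.ly, inter.qaly)
    rows = [
        ("Cost (VND)", round(c.cost), round(i.cost)),
        ("LYs", round(c.ly, 2), round(i.ly, 2)),
        ("QALYs", round(c.qaly, 2), round(i.qaly, 2)),
        ("Incremental cost", "", round(i.cost - c.cost)),
        ("Incremental LY", "", round(i.ly - c.ly, 2)),
        ("Incremental QALY", "", round(i.qaly - c.qaly, 2)),
        ("ICER/LY (VND/LY)", "", _icer_cell(result.icer_per_ly)
         if discounted else ""),
        ("ICER/QALY (VND/QALY)", "", _icer_cell(result.icer_per_qaly)
         if discounted else ""),
    ]
    return pd.DataFrame(rows, columns=["", "Comparison", "Intervention"])
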
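"""Annual per-state costs from unit costs, frequencies and programme costs.

Costing takes a limited societal perspective: each encounter costs its
medical fee plus the patient-borne non-medical components (travel,
meals, other) for its setting.  Encounter frequencies are per
person-year conditional on being in the state, so the expected annual
state cost is sum over levels of frequency x encounter cost.

State-to-encounter mapping: inpatient admissions and acute-CVD
admission fees attach to the acute-CVD state; outpatient visits attach
to hypertension (provincial/district fees) and to stable CVD
(central/provincial fees).  Level/service combinations without a unit
cost contribute zero and are logged.

The programme (intervention) cost has two modes: ``trial`` sums design,
implementation and monitoring-and-evaluation; ``scale_up`` keeps only
implementation, the component that survives a national roll-out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from .markov import HealthState, INTERVENTION

logger = logging.getLogger(__name__)

LEVELS = ("central", "provincial", "district")
SERVICES = ("acute_cvd", "stable_cvd", "hypertension")
SETTINGS = ("inpatient", "outpatient")

#: GDP per capita of Vietnam in 2021 (fixed printed constants, VND / USD).
GDP_PER_CAPITA_VND = 86_400_000
GDP_PER_CAPITA_USD = 3_756


@dataclass(frozen=True)
class UnitCost:
    service: str
    level: str
    setting: str
    medical_cost: float

    def __post_init__(self) -> None:
        if self.service not in SERVICES:
            raise ValueError(f"unknown service {self.service!r}")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.medical_cost < 0:
            raise ValueError("medical cost must be nonnegative")


@dataclass(frozen=True)
class NonMedicalCost:
    """Patient-borne travel/meals/other cost per encounter, by setting."""

    travel: float
    meals: float
    other: float

    def __post_init__(self) -> None:
        if min(self.travel, self.meals, self.other) < 0:
            raise ValueError("non-medical components must be nonnegative")

    @property
    def total(self) -> float:
        return self.travel + self.meals + self.other


@dataclass(frozen=True)
class InterventionCost:
    """Programme cost components, VND per person-year."""

    design: float
    implementation: float
    monitoring_evaluation: float
    mode: str = "trial"

    def __post_init__(self) -> None:
        if min(self.design, self.implementation, self.monitoring_evaluation) < 0:
            raise ValueError("intervention cost components must be nonnegative")
        if self.mode not in ("trial", "scale_up"):
            raise ValueError(f"unknown mode {self.mode!r}")


FrequencySet = Mapping[tuple[str, str], float]  # (setting, level) -> per year
CostTable = Mapping[tuple[str, str, str], float]  # (service, level, setting)
NonMedicalTable = Mapping[str, NonMedicalCost]  # setting -> components


def intervention_annual_cost(ic: InterventionCost) -> float:
    """Programme cost per person-year under the cost's mode."""
    if ic.mode == "trial":
        return ic.design + ic.implementation + ic.monitoring_evaluation
    return ic.implementation


def encounter_cost(
    service: str,
    level: str,
    setting: str,
    unit_costs: CostTable,
    non_medical: NonMedicalTable,
) -> float:
    """Full cost of one encounter: medical fee + setting's non-medical total."""
    key = (service, level, setting)
    if key not in unit_costs:
        raise KeyError(f"no unit cost for {service}/{level}/{setting}")
    nm = non_medical.get(setting)
    return unit_costs[key] + (nm.total if nm is not None else 0.0)


#: Which (service, setting, levels) feed each live state's annual cost.
STATE_ENCOUNTERS: dict[HealthState, tuple[str, str]] = {
    HealthState.HTN: ("hypertension", "outpatient"),
    HealthState.ACUTE_CVD: ("acute_cvd", "inpatient"),
    HealthState.STABLE_CVD: ("stable_cvd", "outpatient"),
}


def annual_state_cost(
    state: HealthState,
    arm: str,
    freq: FrequencySet,
    unit_costs: CostTable,
    non_medical: NonMedicalTable,
    ic: InterventionCost | None = None,
    in_window: bool = True,
) -> float:
    """Expected annual cost of one person-year spent in ``state``.

    Sums frequency x encounter cost over the state's care levels; the
    programme cost is added in the hypertension state of the
    intervention arm while ``in_window`` (the accrual window) holds.
    """
    if state == HealthState.DEAD:
        return 0.0
    service, setting = STATE_ENCOUNTERS[state]
    total = 0.0
    for level in LEVELS:
        f = freq.get((setting, level), 0.0)
        if f < 0:
            raise ValueError(f"negative frequency for {setting}/{level}")
        if (service, level, setting) not in unit_costs:
            if f > 0:
                logger.info(
                    "no printed unit cost for %s/%s/%s; encounters contribute zero",
                    service, level, setting,
                )
            continue
        total += f * encounter_cost(service, level, setting, unit_costs, non_medical)
    if (state == HealthState.HTN and arm == INTERVENTION
            and ic is not None and in_window):
        total += intervention_annual_cost(ic)
    return total


def adjust_to_reference_year(cost_vnd: float) -> float:
    """CPI-standardisation hook; identity because inputs are already 2021 VND."""
    return cost_vnd


def cost_inputs_from_values(values: Mapping[str, float], mode: str = "trial"):
    """Assemble costing tables from a named parameter mapping.

    Returns ``(freq, unit_costs, non_medical, intervention_cost)`` ready
    for :func:`annual_state_cost`.
    """
    freq = {
        ("inpatient", "central"): values["f_inpt_cent"],
        ("inpatient", "provincial"): values["f_inpt_prov"],
        ("inpatient", "district"): values["f_inpt_dist"],
        ("outpatient", "central"): values["f_outpt_cent"],
        ("outpatient", "provincial"): values["f_outpt_prov"],
        ("outpatient", "district"): values["f_outpt_dist"],
    }
    unit_costs = {
        ("acute_cvd", "central", "inpatient"): values["c_acute_central"],
        ("acute_cvd", "provincial", "inpatient"): values["c_acute_prov"],
        ("acute_cvd", "district", "inpatient"): values["c_acute_dist"],
        ("stable_cvd", "central", "outpatient"): values["c_stable_central"],
        ("stable_cvd", "provincial", "outpatient"): values["c_stable_prov"],
        ("hypertension", "provincial", "outpatient"): values["c_htn_prov"],
        ("hypertension", "district", "outpatient"): values["c_htn_dist"],
    }
    non_medical = {
        "inpatient": NonMedicalCost(
            values["c_travel_inpt"], values["c_meals_inpt"], values["c_other_inpt"]
        ),
        "outpatient": NonMedicalCost(
            values["c_travel_outpt"], values["c_meals_outpt"], values["c_other_outpt"]
        ),
    }
    ic = InterventionCost(
        design=values["c_int_design"],
        implementation=values["c_int_implement"],
        monitoring_evaluation=values["c_int_monitor"],
        mode=mode,
    )
    return freq, unit_costs, non_medical, ic
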
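"""Model input parameters and their uncertainty distributions.

Every model input is a :class:`ParameterSpec` carrying a distribution
family (normal, beta, gamma, or fixed) together with its mean and
standard error in natural units.  Beta and gamma shapes are obtained by
matching the first two moments to the printed mean/SE; 95% ranges for
one-way sensitivity use distribution quantiles for beta/gamma (so bounds
respect the support) and mean ± 1.96·SE for normal.

The packaged fixture ``data/table1_params.csv`` transcribes the study's
input-parameter table; :func:`load_parameter_table` reads any file in
the same dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FAMILIES = ("normal", "beta", "gamma", "fixed")

#: Every parameter name the lifetime model consumes (the 38 uncertain /
#: point inputs; discount rates live in :class:`DiscountRates`).
MODEL_PARAMETER_NAMES: tuple[str, ...] = (
    "sbp_int_m", "sbp_int_f", "smoke_int_m", "smoke_int_f",
    "sbp_com_m", "sbp_com_f", "smoke_com_m", "smoke_com_f",
    "mort_cvd_m", "mort_cvd_f",
    "c_int_design", "c_int_implement", "c_int_monitor",
    "c_acute_central", "c_acute_prov", "c_acute_dist",
    "c_stable_central", "c_stable_prov",
    "c_htn_prov", "c_htn_dist",
    "c_travel_inpt", "c_travel_outpt", "c_meals_inpt", "c_meals_outpt",
    "c_other_inpt", "c_other_outpt",
    "f_inpt_cent", "f_inpt_prov", "f_inpt_dist",
    "f_outpt_cent", "f_outpt_prov", "f_outpt_dist",
    "u_htn_m", "u_htn_f", "u_stable_m", "u_stable_f",
    "u_acute_m", "u_acute_f",
)


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta shape parameters whose mean and SD equal ``mean`` and ``se``.

    Closed form: nu = mean(1-mean)/se^2 - 1; alpha = mean*nu;
    beta = (1-mean)*nu.  Requires 0 < mean < 1 and se^2 < mean(1-mean).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must lie in (0, 1); got {mean}")
    if se <= 0.0:
        raise ValueError(f"beta se must be positive; got {se}")
    var = se * se
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible se for beta: se^2={var:g} >= mean(1-mean)="
            f"{mean * (1 - mean):g}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, scale) with mean ``mean`` and SD ``se``.

    shape = (mean/se)^2, scale = se^2/mean.
    """
    if mean <= 0.0 or se <= 0.0:
        raise ValueError(f"gamma requires mean > 0 and se > 0; got {mean}, {se}")
    return (mean / se) ** 2, se * se / mean


@dataclass(frozen=True)
class ParameterSpec:
    """One model input: distribution family plus mean/SE in natural units."""

    name: str
    family: str
    mean: float
    se: float = 0.0
    unit: str = ""
    group: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"{self.name}: unknown family {self.family!r}; "
                f"expected one of {FAMILIES}"
            )
        if self.se < 0.0:
            raise ValueError(f"{self.name}: se must be nonnegative")
        if self.family == "fixed":
            return
        if self.se == 0.0:
            logger.warning(
                "%s: se=0 on family %s degrades to a point mass",
                self.name, self.family,
            )
            return
        # validate moment-matching feasibility eagerly
        if self.family == "beta":
            beta_from_moments(self.mean, self.se)
        elif self.family == "gamma":
            gamma_from_moments(self.mean, self.se)

    @property
    def is_point_mass(self) -> bool:
        """Fixed family, or a degenerate SE of zero."""
        return self.family == "fixed" or self.se == 0.0

    def distribution(self):
        """The moment-matched frozen scipy distribution (non-degenerate only)."""
        if self.is_point_mass:
            raise ValueError(f"{self.name}: point mass has no distribution")
        if self.family == "normal":
            return stats.norm(self.mean, self.se)
        if self.family == "beta":
            a, b = beta_from_moments(self.mean, self.se)
            return stats.beta(a, b)
        a, scale = gamma_from_moments(self.mean, self.se)
        return stats.gamma(a, scale=scale)


def ci95(spec: ParameterSpec) -> tuple[float, float]:
    """95% range used by the one-way sensitivity analysis.

    Normal: mean +/- 1.96 SE.  Beta/gamma: 2.5% and 97.5% quantiles of
    the moment-matched distribution, so bounds stay inside the support.
    A degenerate SE of zero gives the point interval (mean, mean).
    """
    if spec.family == "fixed":
        raise ValueError(f"{spec.name}: fixed parameter has no 95% range")
    if spec.se == 0.0:
        return spec.mean, spec.mean
    if spec.family == "normal":
        return spec.mean - 1.96 * spec.se, spec.mean + 1.96 * spec.se
    dist = spec.distribution()
    return float(dist.ppf(0.025)), float(dist.ppf(0.975))


def sample_parameter(spec: ParameterSpec, rng: np.random.Generator) -> float:
    """One random draw from the spec's moment-matched distribution.

    Fixed specs (and SE-zero point masses) return the mean unchanged.
    """
    if spec.is_point_mass:
        return spec.mean
    if spec.family == "normal":
        return float(rng.normal(spec.mean, spec.se))
    if spec.family == "beta":
        a, b = beta_from_moments(spec.mean, spec.se)
        return float(rng.beta(a, b))
    shape, scale = gamma_from_moments(spec.mean, spec.se)
    return float(rng.gamma(shape, scale))


@dataclass(frozen=True)
class ParameterSet:
    """Realized values for every model input, with provenance."""

    values: Mapping[str, float]
    provenance: str = "means"

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def missing(self, required: Iterable[str] = MODEL_PARAMETER_NAMES) -> list[str]:
        return [n for n in required if n not in self.values]


@dataclass(frozen=True)
class DiscountRates:
    """Annual discount rates; base case 3% for both costs and effects."""

    cost_rate: float = 0.03
    effect_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.cost_rate < 0 or self.effect_rate < 0:
            raise ValueError("discount rates must be nonnegative")


def parameter_means(specs: Iterable[ParameterSpec]) -> ParameterSet:
    """Point-estimate parameter set (every parameter at its mean)."""
    return ParameterSet({s.name: s.mean for s in specs}, provenance="means")


def load_parameter_table(
    path, required: Iterable[str] = MODEL_PARAMETER_NAMES
) -> tuple[list[ParameterSpec], list[str]]:
    """Read a delimited parameter table into specs plus a validation report.

    The file needs columns ``name, family, mean, se`` (``unit, group,
    source`` optional).  Returns ``(specs, report)`` where ``report``
    lists one line per model-required name absent from the file.
    Unknown families, malformed numbers and duplicate names raise with
    the offending row number.
    """
    df = pd.read_csv(path, sep=None, engine="python", skip_blank_lines=True)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("name", "family", "mean", "se"):
        if col not in df.columns:
            raise ValueError(f"parameter table missing column {col!r}")
    specs: list[ParameterSpec] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        name = str(row["name"]).strip()
        if name in seen:
            raise ValueError(f"row {rowno}: duplicate parameter name {name!r}")
        seen.add(name)
        family = str(row["family"]).strip().lower()
        try:
            mean = float(row["mean"])
            se = float(row["se"]) if pd.notna(row["se"]) else 0.0
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {rowno}: malformed number ({exc})") from None
        try:
            spec = ParameterSpec(
                name=name, family=family, mean=mean, se=se,
                unit=str(row.get("unit", "") or ""),
                group=str(row.get("group", "") or ""),
                source=str(row.get("source", "") or ""),
            )
        except ValueError as exc:
            raise ValueError(f"row {rowno}: {exc}") from None
        specs.append(spec)
    report = [f"missing required parameter: {n}" for n in required if n not in seen]
    for line in report:
        logger.warning(line)
    return specs, report


def load_default_parameters() -> list[ParameterSpec]:
    """The packaged study parameter table (38 specs)."""
    with resources.as_file(
        resources.files("cohortcea.data") / "table1_params.csv"
    ) as p:
        specs, report = load_parameter_table(p)
    if report:  # pragma: no cover - packaged fixture is complete
        raise RuntimeError("packaged parameter table incomplete: " + "; ".join(report))
    return specs
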
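"""Annual transition-probability ingredients.

Three sources feed the transition matrices: (1) an annual acute-CVD
event probability obtained from a pluggable k-year risk equation and
annualized under a constant-hazard assumption; (2) background all-cause
mortality from a life table of annual death probabilities qx by age and
sex; (3) an excess CVD death rate added on the hazard scale in the
acute/stable CVD states.

The risk equation is a plug-in point: any callable satisfying
:class:`RiskEquation` (k-year risk in [0,1], monotone nondecreasing in
SBP, smoking and age) can replace the packaged synthetic logistic
stand-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Protocol, runtime_checkable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)


def annualize_risk(p_k: float, k: float) -> float:
    """Convert a k-year event probability to an annual one.

    Constant hazard over the horizon: ``1 - (1 - p_k)**(1/k)``.
    """
    if not 0.0 <= p_k < 1.0:
        raise ValueError(f"k-year risk must lie in [0, 1); got {p_k}")
    if k < 1:
        raise ValueError(f"horizon must be >= 1 year; got {k}")
    return 1.0 - (1.0 - p_k) ** (1.0 / k)


def rate_to_prob(rate: float) -> float:
    """Annual rate -> annual probability, p = 1 - exp(-rate)."""
    if rate < 0:
        raise ValueError(f"rate must be nonnegative; got {rate}")
    return -np.expm1(-rate)


def prob_to_annual_rate(p: float) -> float:
    """Annual probability -> annual rate, the inverse of :func:`rate_to_prob`."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must lie in [0, 1); got {p}")
    return -np.log1p(-p)


@dataclass(frozen=True)
class RiskProfile:
    """Covariates of the modelled cohort at one cycle.

    ``smoking`` is the cohort smoking *prevalence* (the cohort model
    tracks fractions, not individuals); ``total_cholesterol`` is
    optional and unused by the default equation.
    """

    age: float
    sex: str
    sbp: float
    smoking: float
    total_cholesterol: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}; got {self.sex!r}")
        if not 30 <= self.age <= 110:
            raise ValueError(f"age out of range [30, 110]: {self.age}")
        if not 70 <= self.sbp <= 250:
            raise ValueError(f"sbp out of range [70, 250]: {self.sbp}")
        if not 0.0 <= self.smoking <= 1.0:
            raise ValueError(f"smoking prevalence out of [0, 1]: {self.smoking}")


@runtime_checkable
class RiskEquation(Protocol):
    """Contract for a pluggable k-year acute-CVD risk equation."""

    horizon_years: float
    manifest: Mapping

    def k_year_risk(self, age, sex: str, sbp, smoker) -> np.ndarray | float:
        """k-year first-event risk in [0, 1]; vectorized over age/sbp."""
        ...


class LogisticRiskEquation:
    """Logistic k-year risk in age, sex, SBP and smoking status.

    The packaged default manifest is a clearly-labelled synthetic
    stand-in; load a manifest for a validated tool to reproduce
    real-world numbers.  Cholesterol is intentionally absent.
    """

    def __init__(self, manifest: Mapping):
        self.manifest = dict(manifest)
        self.horizon_years = float(manifest["horizon_years"])
        c = manifest["coefficients"]
        self._b0 = float(c["intercept"])
        self._b_age = float(c["age_per_year"])
        self._b_male = float(c["male"])
        self._b_sbp = float(c["sbp_per_mmhg"])
        self._b_smoke = float(c["smoker"])
        centering = manifest.get("centering", {})
        self._age0 = float(centering.get("age", 0.0))
        self._sbp0 = float(centering.get("sbp", 0.0))
        self.validity = {
            k: tuple(v) for k, v in manifest.get("validity", {}).items()
        }

    @classmethod
    def from_manifest(cls, path: str | Path) -> "LogisticRiskEquation":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def in_validity_range(self, age: float, sbp: float) -> bool:
        lo, hi = self.validity.get("age", (-np.inf, np.inf))
        ok = lo <= age <= hi
        lo, hi = self.validity.get("sbp", (-np.inf, np.inf))
        return ok and lo <= sbp <= hi

    def k_year_risk(self, age, sex: str, sbp, smoker):
        if sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}; got {sex!r}")
        age = np.asarray(age, dtype=float)
        sbp = np.asarray(sbp, dtype=float)
        logit = (
            self._b0
            + self._b_age * (age - self._age0)
            + self._b_male * (sex == MALE)
            + self._b_sbp * (sbp - self._sbp0)
            + self._b_smoke * np.asarray(smoker, dtype=float)
        )
        p = 1.0 / (1.0 + np.exp(-logit))
        return p if p.ndim else float(p)


def default_risk_equation() -> LogisticRiskEquation:
    """The packaged synthetic stand-in equation."""
    with resources.as_file(
        resources.files("cohortcea.data") / "risk_equation_synthetic.yaml"
    ) as p:
        return LogisticRiskEquation.from_manifest(p)


def annual_acute_cvd_prob(profile: RiskProfile, eq: RiskEquation) -> float:
    """Annual probability of an acute CVD event for the cohort profile.

    The equation is evaluated separately for smokers and non-smokers,
    each k-year risk is annualized, and the two annual probabilities are
    mixed by the cohort smoking prevalence.
    """
    if hasattr(eq, "in_validity_range") and not eq.in_validity_range(
        profile.age, profile.sbp
    ):
        logger.warning(
            "profile age=%s sbp=%s outside the risk equation's validity range",
            profile.age, profile.sbp,
        )
    k = eq.horizon_years
    p_smoker = annualize_risk(float(eq.k_year_risk(profile.age, profile.sex, profile.sbp, 1.0)), k)
    p_nonsmoker = annualize_risk(float(eq.k_year_risk(profile.age, profile.sex, profile.sbp, 0.0)), k)
    s = profile.smoking
    return s * p_smoker + (1.0 - s) * p_nonsmoker


class LifeTable:
    """Annual all-cause death probabilities qx by integer age and sex."""

    def __init__(self, qx: Mapping[str, np.ndarray], start_age: int):
        self._qx = {s: np.asarray(q, dtype=float) for s, q in qx.items()}
        self.start_age = int(start_age)
        for sex, q in self._qx.items():
            if np.any((q < 0) | (q > 1)):
                raise ValueError(f"{sex}: qx values must lie in [0, 1]")
        lengths = {len(q) for q in self._qx.values()}
        if len(lengths) != 1:
            raise ValueError("all sexes must cover the same age span")
        self.terminal_age = self.start_age + lengths.pop() - 1

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        """Build from a frame with columns ``age, sex, qx``.

        Ages must be contiguous integers within each sex.
        """
        qx: dict[str, np.ndarray] = {}
        starts = set()
        for sex, sub in df.groupby("sex"):
            sub = sub.sort_values("age")
            ages = sub["age"].to_numpy()
            if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
                raise ValueError(f"{sex}: ages must be contiguous integers")
            qx[str(sex)] = sub["qx"].to_numpy(dtype=float)
            starts.add(int(ages[0]))
        if len(starts) != 1:
            raise ValueError("all sexes must start at the same age")
        return cls(qx, starts.pop())

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"age": self.start_age + i, "sex": sex, "qx": q}
            for sex, qs in sorted(self._qx.items())
            for i, q in enumerate(qs)
        ]
        return pd.DataFrame(rows)

    def qx(self, age: int, sex: str) -> float:
        """Probability of death within one year at ``age`` for ``sex``."""
        if sex not in self._qx:
            raise KeyError(f"no life-table entries for sex {sex!r}")
        idx = int(age) - self.start_age
        if idx < 0 or idx >= len(self._qx[sex]):
            raise ValueError(
                f"age {age} outside life table [{self.start_age}, {self.terminal_age}]"
            )
        return float(self._qx[sex][idx])

    def qx_slice(self, ages: np.ndarray, sex: str) -> np.ndarray:
        """Vectorized qx lookup for an array of integer ages."""
        ages = np.asarray(ages, dtype=int)
        idx = ages - self.start_age
        if idx.min() < 0 or idx.max() >= len(self._qx[sex]):
            raise ValueError("ages outside the life table span")
        return self._qx[sex][idx]


def background_death_prob(lt: LifeTable, age: int, sex: str) -> float:
    """Annual all-cause death probability from the life table."""
    return lt.qx(age, sex)


@dataclass(frozen=True)
class CvdExcessMortality:
    """Excess annual CVD death rate applied in the acute/stable CVD states."""

    male: float
    female: float

    def __post_init__(self) -> None:
        if self.male < 0 or self.female < 0:
            raise ValueError("excess mortality rates must be nonnegative")

    def rate(self, sex: str) -> float:
        if sex == MALE:
            return self.male
        if sex == FEMALE:
            return self.female
        raise ValueError(f"sex must be one of {SEXES}; got {sex!r}")


def cvd_state_death_prob(qx: float, excess: CvdExcessMortality, sex: str) -> float:
    """Annual death probability in a CVD state.

    Background mortality and the excess CVD rate combine additively on
    the hazard scale, then convert back to a probability (capped at 1),
    which guarantees a valid probability never below qx.
    """
    if not 0.0 <= qx <= 1.0:
        raise ValueError(f"qx must lie in [0, 1]; got {qx}")
    if qx == 1.0:
        return 1.0
    total_rate = prob_to_annual_rate(qx) + excess.rate(sex)
    # the outer max/min guard the hazard<->probability float round-trip
    return max(min(rate_to_prob(total_rate), 1.0), qx)
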
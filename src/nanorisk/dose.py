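"""Chronic-daily-intake chain and point-of-departure unit conversion.

The dose chain has three stages:

``cdi``
    Annualised chronic daily intake (mg/kg/day) from an air concentration:
    ``C * CF * IR * ED / (BW * AT)`` with C in ug/m^3, CF = 0.001 mg/ug,
    IR the inhalation rate (m^3/day), ED the exposed days per year, BW body
    weight (kg) and AT the averaging constant.

``cdi_25``
    Cumulative occupational dose (mg/kg) over the working career:
    ``CDI * 250 working days * YE years / life_expectancy``.

``cdi_adj``
    The cumulative dose re-averaged over lifetime days (mg/kg/day):
    ``CDI_25 / (life_expectancy_years * 365)``.  This is the exposure term
    of the margin of exposure.

Points of departure from in-vitro surface doses are converted via
``ug/cm^2 -> ug/m^2 (x 10^4) -> ug/m^3 (unity-thickness assumption)
-> mg/m^3 (/1000)`` and then run through the same intake form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import DivisionDomainError, InvalidInputError
from .exposure import ExposureFactorSet, WORKING_DAYS_PER_YEAR

#: Days per year for lifetime averaging (no leap days).
DAYS_PER_YEAR = 365.0

#: Compatibility divisor: published tables divide both sexes' cumulative
#: dose by the male life expectancy.
AS_PRINTED_DIVISOR = 64.0


@dataclass(frozen=True)
class PodSpec:
    """Point of departure anchoring risk characterisation (mg/kg/day)."""

    material: str
    value: float
    source: Literal["in_vitro_converted", "literature_noael"] = "literature_noael"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise InvalidInputError("POD must be positive")


#: Default points of departure: silver and gold from in-vitro bronchial
#: epithelial response concentrations; graphene and MWCNT from literature
#: no-observed-adverse-effect levels.
PODS: dict[str, PodSpec] = {
    "silver": PodSpec("silver", 53.7, "in_vitro_converted"),
    "gold": PodSpec("gold", 536.7, "in_vitro_converted"),
    "graphene": PodSpec("graphene", 0.98, "literature_noael"),
    "mwcnt": PodSpec("mwcnt", 3.02, "literature_noael"),
}


def cdi(c, cf, ir, ed, bw, at):
    """Chronic daily intake (mg/kg/day): ``c*cf*ir*ed / (bw*at)``.

    Vectorised over aligned array inputs; linear in ``c``.
    """
    c, cf, ir, ed, bw, at = map(np.asarray, (c, cf, ir, ed, bw, at))
    if np.any(bw <= 0) or np.any(at <= 0):
        raise DivisionDomainError("body weight and averaging time must be positive")
    if np.any(c < 0) or np.any(cf <= 0) or np.any(ir <= 0) or np.any(ed <= 0):
        raise InvalidInputError("factors must be positive and concentration >= 0")
    out = c * cf * ir * ed / (bw * at)
    return float(out) if out.ndim == 0 else out


def cdi_25(cdi_value, ye, life_expectancy):
    """Cumulative occupational dose (mg/kg): ``cdi * 250 * ye / life_expectancy``."""
    cdi_value, ye, life_expectancy = map(np.asarray, (cdi_value, ye, life_expectancy))
    if np.any(life_expectancy <= 0):
        raise DivisionDomainError("life expectancy must be positive")
    if np.any(cdi_value < 0) or np.any(ye <= 0):
        raise InvalidInputError("cdi must be >= 0 and ye positive")
    out = cdi_value * WORKING_DAYS_PER_YEAR * ye / life_expectancy
    return float(out) if out.ndim == 0 else out


def cdi_adj(cdi_25_value, life_expectancy_years):
    """Lifetime-averaged intake (mg/kg/day): ``cdi_25 / (years * 365)``."""
    cdi_25_value, life_expectancy_years = map(
        np.asarray, (cdi_25_value, life_expectancy_years))
    if np.any(life_expectancy_years <= 0):
        raise DivisionDomainError("life expectancy must be positive")
    if np.any(cdi_25_value < 0):
        raise InvalidInputError("cdi_25 must be >= 0")
    out = cdi_25_value / (life_expectancy_years * DAYS_PER_YEAR)
    return float(out) if out.ndim == 0 else out


@dataclass
class DoseResult:
    """The three dose-chain stages plus an echo of the factors used."""

    cdi: float
    cdi_25: float
    cdi_adj: float
    sex: str
    inputs_echo: dict = field(default_factory=dict)


def dose_chain(
    c: float,
    factors: ExposureFactorSet,
    *,
    as_printed: bool = False,
) -> DoseResult:
    """Full deterministic CDI -> CDI_25 -> CDI_adj chain for one sex.

    Uses the factor set's point values: ED in the intake equation is the
    exposed days per year (the exposure-frequency mode) and AT is the
    sex-specific life-expectancy constant.  With ``as_printed`` the
    cumulative-dose divisor is 64.0 for both sexes, matching the published
    tables' female rows instead of the sex-specific rule.
    """
    divisor = AS_PRINTED_DIVISOR if as_printed else factors.life_expectancy
    daily = cdi(c, factors.cf, factors.inhalation_rate, factors.ef_point,
                factors.body_weight, factors.life_expectancy)
    cumulative = cdi_25(daily, factors.ye, divisor)
    adjusted = cdi_adj(cumulative, factors.life_expectancy)
    return DoseResult(
        cdi=daily, cdi_25=cumulative, cdi_adj=adjusted, sex=factors.sex,
        inputs_echo={
            "c": c, "cf": factors.cf, "ir": factors.inhalation_rate,
            "ed_days_per_year": factors.ef_point, "bw": factors.body_weight,
            "at": factors.life_expectancy, "ye": factors.ye,
            "cdi25_divisor": divisor,
        },
    )


def pod_from_surface_dose(surface_dose: float, factors: ExposureFactorSet) -> float:
    """Convert an in-vitro surface dose (ug/cm^2) to a POD in mg/kg/day.

    ``ug/cm^2 * 10^4 -> ug/m^2``, taken as ``ug/m^3`` under the
    conservative unity-thickness assumption, ``/1000 -> mg/m^3``, then run
    through the intake form with the supplied factors (CF omitted because
    the concentration is already in mg).
    """
    if surface_dose < 0:
        raise InvalidInputError("surface dose must be non-negative")
    conc_mg_m3 = surface_dose * 10_000.0 / 1000.0
    return cdi(conc_mg_m3, 1.0, factors.inhalation_rate, factors.ef_point,
               factors.body_weight, factors.life_expectancy)


def surface_dose_to_mg_m3(surface_dose: float) -> float:
    """The intermediate air-concentration equivalent (mg/m^3) of a surface dose."""
    if surface_dose < 0:
        raise InvalidInputError("surface dose must be non-negative")
    return surface_dose * 10_000.0 / 1000.0
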
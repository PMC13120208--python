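"""Exposure factors and time/frequency/duration adjustment of air concentrations.

A laboratory worker is not exposed continuously: the workplace concentration
is scaled by the fraction of the day exposed (ET/24), the fraction of the
year worked (EF/365), and the worked fraction of the averaging period
(ED/AT).  The defaults encode a South African laboratory scenario: sex-
specific inhalation rate and body weight, 5/6/8 h/day exposure time,
51/63/83 days/yr frequency, 20/25/30 yr duration, and life expectancies of
64.0 yr (male) and 69.6 yr (female).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvalidFactorError, InvalidInputError
from .montecarlo import DistributionSpec

#: Unit conversion ug -> mg.
CF_MG_PER_UG = 0.001

#: Working days per year used to annualise the daily intake.
WORKING_DAYS_PER_YEAR = 250

#: Occupational exposure period for cumulative dose (years).
YE_YEARS = 25.0


@dataclass(frozen=True)
class ExposureFactorSet:
    """Sex-specific exposure factors with their uncertainty distributions.

    ``inhalation_rate`` m^3/day, ``body_weight`` kg, ``life_expectancy`` yr;
    ET h/day, EF days/yr, ED yr carry triangular distributions for the
    probabilistic chain and a point value (the triangular mode) for the
    deterministic chain.
    """

    sex: str
    inhalation_rate: float
    body_weight: float
    life_expectancy: float
    inhalation_rate_dist: DistributionSpec
    body_weight_dist: DistributionSpec
    exposure_time: DistributionSpec = field(
        default_factory=lambda: DistributionSpec.triangular(5, 6, 8))
    exposure_frequency: DistributionSpec = field(
        default_factory=lambda: DistributionSpec.triangular(51, 63, 83))
    exposure_duration: DistributionSpec = field(
        default_factory=lambda: DistributionSpec.triangular(20, 25, 30))
    ye: float = YE_YEARS
    cf: float = CF_MG_PER_UG

    def __post_init__(self) -> None:
        for name in ("inhalation_rate", "body_weight", "life_expectancy", "ye", "cf"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")

    @property
    def et_point(self) -> float:
        return self.exposure_time.params.get("mode",
                                             self.exposure_time.params.get("value"))

    @property
    def ef_point(self) -> float:
        return self.exposure_frequency.params.get(
            "mode", self.exposure_frequency.params.get("value"))

    @property
    def ed_point(self) -> float:
        return self.exposure_duration.params.get(
            "mode", self.exposure_duration.params.get("value"))

    @classmethod
    def male(cls) -> "ExposureFactorSet":
        return cls(
            sex="male", inhalation_rate=17.48, body_weight=65.2,
            life_expectancy=64.0,
            inhalation_rate_dist=DistributionSpec.uniform_pm(17.48, 2.81),
            body_weight_dist=DistributionSpec.uniform_pm(65.2, 0.301),
        )

    @classmethod
    def female(cls) -> "ExposureFactorSet":
        return cls(
            sex="female", inhalation_rate=13.67, body_weight=67.8,
            life_expectancy=69.6,
            inhalation_rate_dist=DistributionSpec.uniform_pm(13.67, 2.28),
            body_weight_dist=DistributionSpec.uniform_pm(67.8, 0.261),
        )

    @classmethod
    def for_sex(cls, sex: str) -> "ExposureFactorSet":
        if sex == "male":
            return cls.male()
        if sex == "female":
            return cls.female()
        raise InvalidInputError(f"unknown sex {sex!r}")


def adjust_concentration(c_air, et, ef, ed, at):
    """Time/frequency/duration-adjusted air concentration (ug/m^3).

    ``c_air * (et/24) * (ef/365) * (ed/at)`` with ET in h/day, EF in
    days/yr, ED and AT in years.  Accepts scalars or aligned arrays.
    Never exceeds ``c_air`` while ET <= 24, EF <= 365 and ED <= AT.
    """
    import numpy as np

    c_air, et, ef, ed, at = map(np.asarray, (c_air, et, ef, ed, at))
    if np.any(c_air < 0):
        raise InvalidInputError("concentration must be non-negative")
    if np.any(et <= 0) or np.any(et > 24):
        raise InvalidFactorError("exposure time must be in (0, 24] h/day")
    if np.any(ef <= 0) or np.any(ef > 365):
        raise InvalidFactorError("exposure frequency must be in (0, 365] days/yr")
    if np.any(ed <= 0) or np.any(at <= 0):
        raise InvalidFactorError("exposure duration and averaging time must be positive")
    out = c_air * (et / 24.0) * (ef / 365.0) * (ed / at)
    return float(out) if out.ndim == 0 else out


def adjust_concentration_point(c_air: float, factors: ExposureFactorSet) -> float:
    """Deterministic adjustment using the factor set's point values."""
    return adjust_concentration(
        c_air, factors.et_point, factors.ef_point, factors.ed_point,
        factors.life_expectancy,
    )
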
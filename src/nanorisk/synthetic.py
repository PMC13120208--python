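"""Synthetic particle-sizer sessions with known ground truth.

Emulates what a scanning mobility / optical particle sizer records during
laboratory nanomaterial work: a lognormally fluctuating background aerosol,
and an emission session in which the synthesis adds particles on top of
that background.  Each timestamp's total number concentration is drawn
lognormally (GM/GSD on the total), then apportioned across size bins by a
discretised lognormal number-size distribution (CDF differences over the
bin edges — exact discretisation).  Draws are i.i.d. across timestamps;
real instrument series are autocorrelated, but the session-averaging the
pipeline applies is insensitive to that.

The ground truth stored with each scenario gives the expected net per-bin
concentrations and the closed-form mass concentration, so pipeline
estimates can be checked against known values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .aerosol import (
    MASS_CONVERSION_CONSTANT,
    BinnedConcentrationSeries,
    MaterialSpec,
    MATERIALS,
    SizeBinGrid,
)
from .errors import ConfigurationError, InvalidSpecError


def lognormal_mean(gm: float, gsd: float) -> float:
    """Arithmetic mean of a lognormal given geometric mean and geometric SD."""
    return gm * math.exp(0.5 * math.log(gsd) ** 2)


@dataclass(frozen=True)
class EmissionScenario:
    """Generator configuration for one background/emission session pair.

    ``background_gm``/``emission_gm`` are geometric means of the *total*
    number concentration (#/cm^3) per timestamp; ``size_mode``/``size_gsd``
    parameterise the lognormal number-size distribution apportioning the
    total across bins.
    """

    material: MaterialSpec
    instrument_profile: str = "nanoscan"
    background_gm: float = 1_000.0
    background_gsd: float = 1.5
    emission_gm: float = 10_000.0
    emission_gsd: float = 1.5
    size_mode: float = 50.0          # nm, geometric mean diameter
    size_gsd: float = 1.6
    session_minutes: float = 360.0
    sampling_interval_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_gm", "emission_gm", "size_mode",
                     "session_minutes", "sampling_interval_s"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive")
        for name in ("background_gsd", "emission_gsd", "size_gsd"):
            if getattr(self, name) < 1.0:
                raise InvalidSpecError(f"{name} must be >= 1")

    @property
    def n_timestamps(self) -> int:
        return max(1, int(self.session_minutes * 60 / self.sampling_interval_s))

    def grid(self) -> SizeBinGrid:
        return SizeBinGrid.from_profile(self.instrument_profile)

    def bin_weights(self) -> np.ndarray:
        """Fraction of the total count in each bin (lognormal CDF differences).

        Renormalised over the instrument's range so the weights sum to one;
        a near-monodisperse distribution (size_gsd -> 1) collapses onto the
        bin containing ``size_mode``.
        """
        edges = self.grid().bin_edges
        if self.size_gsd == 1.0:
            w = np.zeros(edges.size - 1)
            idx = int(np.clip(np.searchsorted(edges, self.size_mode, "right") - 1,
                              0, w.size - 1))
            w[idx] = 1.0
            return w
        cdf = stats.lognorm.cdf(edges, s=math.log(self.size_gsd),
                                scale=self.size_mode)
        w = np.diff(cdf)
        total = w.sum()
        if total <= 0:
            raise ConfigurationError(
                "size distribution has no mass inside the instrument range")
        return w / total

    # -- ground truth -------------------------------------------------------
    def truth(self) -> dict:
        """Expected net concentrations and closed-form mass concentration."""
        w = self.bin_weights()
        net_total = lognormal_mean(self.emission_gm, self.emission_gsd) - \
            lognormal_mean(self.background_gm, self.background_gsd)
        net_per_bin = net_total * w
        d = self.grid().bin_midpoints
        mass = float(np.sum(
            MASS_CONVERSION_CONSTANT * self.material.density
            * np.clip(net_per_bin, 0.0, None) * (math.pi / 6.0) * d**3))
        return {
            "net_total": net_total,
            "net_per_bin": net_per_bin,
            "mass_ug_m3": mass,
            "bin_weights": w,
        }


def _draw_session(
    scenario: EmissionScenario,
    gm: float,
    gsd: float,
    kind: str,
    rng: np.random.Generator,
) -> BinnedConcentrationSeries:
    n = scenario.n_timestamps
    totals = np.exp(rng.normal(math.log(gm), math.log(gsd) if gsd > 1 else 0.0,
                               size=n))
    values = totals[:, None] * scenario.bin_weights()[None, :]
    ts = pd.date_range("2025-01-01 09:00", periods=n,
                       freq=pd.Timedelta(seconds=scenario.sampling_interval_s))
    return BinnedConcentrationSeries(scenario.grid(), ts, values,
                                     session_kind=kind)  # type: ignore[arg-type]


def generate_session(
    scenario: EmissionScenario,
) -> tuple[BinnedConcentrationSeries, BinnedConcentrationSeries, dict]:
    """Generate a (background, emission, truth) triple for a scenario.

    Identical seeds give identical series; the truth record carries the
    expected net per-bin concentrations and closed-form mass.
    """
    rng = np.random.default_rng(scenario.seed)
    background = _draw_session(scenario, scenario.background_gm,
                               scenario.background_gsd, "background", rng)
    emission = _draw_session(scenario, scenario.emission_gm,
                             scenario.emission_gsd, "emission", rng)
    return background, emission, scenario.truth()


def preset_scenarios(seed: int = 0) -> dict[str, EmissionScenario]:
    """The five laboratory scenario presets.

    Emission geometric means follow the measured session totals for each
    material and instrument; backgrounds are set to a tenth of the emission
    (the studied sessions were strongly emission-dominated).  GSD 1.5 for
    amplitude fluctuation and the material's nominal size for the mode are
    generator assumptions, not measured values.
    """
    def scen(name, profile, emission_total, size_mode, sub_seed):
        material = MATERIALS[name.split("_")[0]] if name.split("_")[0] in MATERIALS \
            else MATERIALS[name]
        # emission GM chosen so the expected *net* total matches the session total
        gsd = 1.5
        amp = math.exp(0.5 * math.log(gsd) ** 2)
        emission_gm = emission_total / amp / 0.9  # net = 0.9 * E[emission]
        return EmissionScenario(
            material=material, instrument_profile=profile,
            background_gm=emission_gm / 10.0, background_gsd=gsd,
            emission_gm=emission_gm, emission_gsd=gsd,
            size_mode=size_mode, size_gsd=1.6,
            seed=seed * 1000 + sub_seed,
        )

    return {
        "silver": scen("silver", "nanoscan", 1.05e4, 20.0, 1),
        "gold_synthesis": scen("gold", "nanoscan", 7.56e3, 30.0, 2),
        "gold_application": scen("gold", "nanoscan", 635.0, 30.0, 3),
        "graphene": scen("graphene", "nanoscan", 4.05e4, 100.0, 4),
        "mwcnt": scen("mwcnt", "nanoscan", 3.08e4, 50.0, 5),
    }
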
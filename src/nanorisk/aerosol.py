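"""Reduction of size-binned aerosol number concentrations to exposure metrics.

A particle sizer session is a matrix of number concentrations (#/cm^3), one
row per timestamp and one column per size bin.  This module averages
background and emission sessions, forms the net emission by background
subtraction, converts the number concentration to a mass concentration using
spherical-particle volume and bulk density, and reduces the result to an
8-hour-equivalent time-weighted average (TWA) for comparison with
occupational exposure limits (OELs) and nano reference values (NRVs).

Mass conversion.  For bin midpoints :math:`d_i` (nm), bulk density
:math:`\\rho` (g/cm^3) and per-bin net number concentrations :math:`C_{N,i}`
(#/cm^3),

.. math::

    C_m = \\sum_i k\\,\\rho\\,C_{N,i}\\,\\frac{\\pi}{6} d_i^3
    \\qquad [\\mu g/m^3]

with :math:`k = 10^{-9}` the unit-conversion constant: the nm^3 -> cm^3
volume conversion contributes :math:`10^{-21}` and the g per cm^3-of-air ->
ug per m^3-of-air conversion contributes :math:`10^{12}`.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    IncompatibleGridsError,
    InvalidDurationError,
    InvalidGridError,
    InvalidInputError,
)

#: Unit conversion for (nm^3, g/cm^3, #/cm^3) -> ug/m^3.
MASS_CONVERSION_CONSTANT = 1e-9

#: Minutes in a standard 8-hour shift.
SHIFT_MINUTES = 480.0

#: Default laboratory session length (worst-case synthesis scenario, minutes).
DEFAULT_SESSION_MINUTES = 360.0


def bin_midpoints(edges: Sequence[float], rule: str = "geometric") -> np.ndarray:
    """Midpoint diameter of each size bin.

    Parameters
    ----------
    edges
        Strictly increasing, positive bin edges in nm (``n+1`` edges for
        ``n`` bins).
    rule
        ``"geometric"`` (default, standard for log-spaced sizer channels)
        or ``"arithmetic"``.

    Returns
    -------
    numpy.ndarray
        One midpoint per bin, strictly inside its bin.
    """
    e = np.asarray(edges, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise InvalidGridError("need at least two bin edges")
    if np.any(e <= 0) or np.any(np.diff(e) <= 0):
        raise InvalidGridError("bin edges must be positive and strictly increasing")
    if rule == "geometric":
        return np.sqrt(e[:-1] * e[1:])
    if rule == "arithmetic":
        return 0.5 * (e[:-1] + e[1:])
    raise InvalidGridError(f"unknown midpoint rule {rule!r}")


def _log_edges(lo: float, hi: float, n_bins: int) -> np.ndarray:
    return np.geomspace(lo, hi, n_bins + 1)


@dataclass(frozen=True)
class SizeBinGrid:
    """Size-bin layout of a particle sizer.

    The two built-in profiles mirror the instruments used for laboratory
    nanomaterial monitoring: a scanning mobility sizer covering 10-420 nm
    ("nanoscan", 13 log-spaced channels) and an optical sizer covering
    300 nm - 10 um ("ops", 16 log-spaced channels).
    """

    instrument_profile: Literal["nanoscan", "ops", "custom"]
    bin_edges: np.ndarray
    midpoint_rule: str = "geometric"

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        bin_midpoints(edges, self.midpoint_rule)  # validates
        object.__setattr__(self, "bin_edges", edges)

    @property
    def bin_midpoints(self) -> np.ndarray:
        return bin_midpoints(self.bin_edges, self.midpoint_rule)

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @classmethod
    def nanoscan(cls, midpoint_rule: str = "geometric") -> "SizeBinGrid":
        return cls("nanoscan", _log_edges(10.0, 420.0, 13), midpoint_rule)

    @classmethod
    def ops(cls, midpoint_rule: str = "geometric") -> "SizeBinGrid":
        return cls("ops", _log_edges(300.0, 10_000.0, 16), midpoint_rule)

    @classmethod
    def from_profile(cls, profile: str, midpoint_rule: str = "geometric") -> "SizeBinGrid":
        if profile == "nanoscan":
            return cls.nanoscan(midpoint_rule)
        if profile == "ops":
            return cls.ops(midpoint_rule)
        raise InvalidGridError(f"unknown instrument profile {profile!r}")

    @classmethod
    def monodisperse(cls, diameter_nm: float) -> "SizeBinGrid":
        """Single-bin grid whose geometric midpoint equals ``diameter_nm``.

        Convenience for the monodisperse interpretation in which the whole
        aerosol is treated as sitting at the material's nominal primary
        size (e.g. 20 nm silver, 30 nm gold).
        """
        if diameter_nm <= 0:
            raise InvalidGridError("diameter must be positive")
        half = math.sqrt(2.0)
        return cls("custom", np.array([diameter_nm / half, diameter_nm * half]))

    def compatible(self, other: "SizeBinGrid") -> bool:
        return self.bin_edges.shape == other.bin_edges.shape and np.allclose(
            self.bin_edges, other.bin_edges
        )


@dataclass
class BinnedConcentrationSeries:
    """One sizer session: number concentrations per timestamp and size bin."""

    grid: SizeBinGrid
    timestamps: pd.DatetimeIndex
    values: np.ndarray  # (n_timestamps, n_bins), #/cm^3
    session_kind: Literal["background", "emission"] = "emission"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise InvalidInputError("values must be a 2-D matrix (timestamps x bins)")
        if v.shape[0] != len(self.timestamps):
            raise InvalidInputError("row count must equal timestamp count")
        if v.shape[1] != self.grid.n_bins:
            raise InvalidInputError("column count must equal bin count")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise InvalidInputError("concentrations must be finite and non-negative")
        self.values = v

    @property
    def n_timestamps(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class MaterialSpec:
    """Nanomaterial identity and the constants the risk chain needs.

    density in g/cm^3 (bulk), reference_diameter in nm (nominal primary
    particle size), oel_mass in ug/m^3, nrv_number in #/cm^3, rfc in ug/m^3.
    """

    name: str
    density: float
    reference_diameter: float
    oel_mass: float | None = None
    nrv_number: float | None = None
    rfc: float | None = None

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise InvalidInputError("density must be positive")
        if self.reference_diameter <= 0:
            raise InvalidInputError("reference diameter must be positive")


#: Literature defaults: bulk densities, nominal sizes and benchmarks for the
#: five laboratory scenarios.
MATERIALS: dict[str, MaterialSpec] = {
    "silver": MaterialSpec("silver", density=10.49, reference_diameter=20.0,
                           oel_mass=0.19, rfc=0.19),
    "gold": MaterialSpec("gold", density=19.3, reference_diameter=30.0,
                         nrv_number=20_000.0),
    "graphene": MaterialSpec("graphene", density=1.0, reference_diameter=100.0),
    "mwcnt": MaterialSpec("mwcnt", density=1.5, reference_diameter=50.0,
                          oel_mass=1.0, rfc=1.0),
}


def mean_concentration(series: BinnedConcentrationSeries) -> tuple[np.ndarray, float]:
    """Per-bin arithmetic mean over timestamps and the total over bins.

    This is the session-average concentration: the per-bin mean of the raw
    matrix, plus its sum, which is the total particle number concentration
    used against the NRV.
    """
    if series.n_timestamps == 0:
        raise EmptyInputError("series has no timestamps")
    per_bin = series.values.mean(axis=0)
    return per_bin, float(per_bin.sum())


@dataclass
class NetEmission:
    """Background-subtracted per-bin concentration with a clamp report."""

    per_bin: np.ndarray          # clamped at zero, #/cm^3
    raw_difference: np.ndarray   # unclamped emission - background
    clamped: np.ndarray          # bool flags: True where floored at zero

    @property
    def total(self) -> float:
        return float(self.per_bin.sum())


def net_emission(
    emission_mean: np.ndarray,
    background_mean: np.ndarray,
    *,
    emission_grid: SizeBinGrid | None = None,
    background_grid: SizeBinGrid | None = None,
) -> NetEmission:
    """Net emission: per-bin emission mean minus background mean.

    Negative differences (background exceeding emission in a bin) are
    floored at zero and flagged; the raw differences remain on the result.
    """
    if emission_grid is not None and background_grid is not None:
        if not emission_grid.compatible(background_grid):
            raise IncompatibleGridsError("emission and background grids differ")
    e = np.asarray(emission_mean, dtype=float)
    b = np.asarray(background_mean, dtype=float)
    if e.shape != b.shape:
        raise IncompatibleGridsError(
            f"bin counts differ: {e.shape} vs {b.shape}"
        )
    raw = e - b
    clamped = raw < 0
    return NetEmission(per_bin=np.where(clamped, 0.0, raw), raw_difference=raw,
                       clamped=clamped)


def number_to_mass(
    net_per_bin: Sequence[float] | np.ndarray,
    midpoints_nm: Sequence[float] | np.ndarray,
    density: float,
) -> float:
    """Convert per-bin number concentrations to a mass concentration.

    Assumes spherical particles of bulk density at each bin midpoint:
    ``Cm = sum_i k * rho * CN_i * (pi/6) * d_i^3`` in ug/m^3 with
    ``k = 1e-9`` (see module docstring for the unit bookkeeping).
    """
    cn = np.asarray(net_per_bin, dtype=float)
    d = np.asarray(midpoints_nm, dtype=float)
    if cn.shape != d.shape:
        raise InvalidInputError("per-bin counts must align with midpoints")
    if np.any(cn < 0):
        raise InvalidInputError("number concentrations must be non-negative")
    if np.any(d <= 0):
        raise InvalidInputError("midpoints must be positive")
    if density <= 0:
        raise InvalidInputError("density must be positive")
    return float(np.sum(MASS_CONVERSION_CONSTANT * density * cn * (math.pi / 6.0) * d**3))


def mass_concentration_monodisperse(
    total_number: float, material: MaterialSpec
) -> float:
    """Mass concentration treating the whole aerosol as monodisperse.

    Places the entire net number concentration at the material's nominal
    primary diameter.  This single-size shortcut is how total-count tables
    are converted when the full size distribution is not carried forward.
    """
    return number_to_mass(
        [total_number], [material.reference_diameter], material.density
    )


def twa_8h(mass_conc: float, session_minutes: float = DEFAULT_SESSION_MINUTES) -> float:
    """8-hour-equivalent time-weighted average of a session concentration.

    Scales the session-average mass concentration by session length over the
    480-minute shift; exposure outside the session is taken as zero.
    """
    if not (0 < session_minutes <= SHIFT_MINUTES):
        raise InvalidDurationError(
            f"session minutes must be in (0, {SHIFT_MINUTES:g}], got {session_minutes}"
        )
    if mass_conc < 0:
        raise InvalidInputError("mass concentration must be non-negative")
    return mass_conc * session_minutes / SHIFT_MINUTES


# ---------------------------------------------------------------------------
# CSV dialect: "# profile: <name>" comment, then
# timestamp,bin_<lower>_<upper>nm,... one row per timestamp.
# ---------------------------------------------------------------------------

_BIN_COL = re.compile(r"^bin_([0-9.]+)_([0-9.]+)nm$")


def write_session_csv(series: BinnedConcentrationSeries, path_or_buf) -> None:
    """Write a session in the binned-CSV dialect (profile comment + header)."""
    edges = series.grid.bin_edges
    cols = [f"bin_{lo:.12g}_{hi:.12g}nm" for lo, hi in zip(edges[:-1], edges[1:])]
    df = pd.DataFrame(series.values, columns=cols)
    df.insert(0, "timestamp", series.timestamps.astype(str))
    header = f"# profile: {series.grid.instrument_profile}\n# session: {series.session_kind}\n"
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(header)
        df.to_csv(path_or_buf, index=False, float_format="%.6g")
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, float_format="%.6g")


def read_session_csv(path_or_buf, profile: str | None = None) -> BinnedConcentrationSeries:
    """Read a session written by :func:`write_session_csv`.

    The instrument profile is taken from the ``# profile:`` comment line
    unless overridden by the ``profile`` argument.
    """
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    kind = "emission"
    for line in text.splitlines():
        if line.startswith("# profile:") and profile is None:
            profile = line.split(":", 1)[1].strip()
        elif line.startswith("# session:"):
            kind = line.split(":", 1)[1].strip()
    body = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
    df = pd.read_csv(io.StringIO(body))
    if df.empty:
        raise EmptyInputError("session file contains no measurement rows")
    bin_cols = [c for c in df.columns if _BIN_COL.match(c)]
    if not bin_cols:
        raise InvalidGridError("no bin_<lower>_<upper>nm columns found")
    edges = [float(_BIN_COL.match(bin_cols[0]).group(1))]
    edges += [float(_BIN_COL.match(c).group(2)) for c in bin_cols]
    grid = SizeBinGrid(profile or "custom", np.asarray(edges))
    ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
    return BinnedConcentrationSeries(grid, ts, df[bin_cols].to_numpy(float),
                                     session_kind=kind)  # type: ignore[arg-type]


@dataclass
class ReductionReport:
    """Table-2-style reduction of one material/instrument pairing."""

    material: str
    instrument: str
    total_number: float           # net #/cm^3
    mass_conc: float              # ug/m^3
    twa: float                    # 8-h equivalent ug/m^3
    oel_mass: float | None = None
    nrv_number: float | None = None
    clamp_fraction: float = 0.0   # fraction of bins floored at zero

    @property
    def exceeds_oel(self) -> bool | None:
        if self.oel_mass is None:
            return None
        return self.twa > self.oel_mass

    @property
    def exceeds_nrv(self) -> bool | None:
        if self.nrv_number is None:
            return None
        return self.total_number > self.nrv_number


def reduce_sessions(
    background: BinnedConcentrationSeries,
    emission: BinnedConcentrationSeries,
    material: MaterialSpec,
    session_minutes: float = DEFAULT_SESSION_MINUTES,
    *,
    monodisperse: bool = False,
) -> ReductionReport:
    """Full reduction of a background/emission session pair.

    Averages both sessions, subtracts background, converts number to mass
    (per-bin, or via the monodisperse shortcut at the material's nominal
    diameter) and applies the 8-h TWA rule.
    """
    bg_per_bin, _ = mean_concentration(background)
    em_per_bin, _ = mean_concentration(emission)
    net = net_emission(em_per_bin, bg_per_bin,
                       emission_grid=emission.grid, background_grid=background.grid)
    if monodisperse:
        mass = mass_concentration_monodisperse(net.total, material)
    else:
        mass = number_to_mass(net.per_bin, emission.grid.bin_midpoints, material.density)
    return ReductionReport(
        material=material.name,
        instrument=emission.grid.instrument_profile,
        total_number=net.total,
        mass_conc=mass,
        twa=twa_8h(mass, session_minutes),
        oel_mass=material.oel_mass,
        nrv_number=material.nrv_number,
        clamp_fraction=float(net.clamped.mean()),
    )


def comparison_table(reports: Sequence[ReductionReport]) -> pd.DataFrame:
    """TWA-vs-OEL and number-vs-NRV comparison with verdicts."""
    def verdict(flag: bool | None) -> str:
        return "-" if flag is None else ("exceed" if flag else "comply")

    return pd.DataFrame(
        {
            "material": [r.material for r in reports],
            "instrument": [r.instrument for r in reports],
            "total_number_cm3": [r.total_number for r in reports],
            "mass_ug_m3": [r.mass_conc for r in reports],
            "twa_8h_ug_m3": [r.twa for r in reports],
            "oel_ug_m3": [r.oel_mass for r in reports],
            "oel_verdict": [verdict(r.exceeds_oel) for r in reports],
            "nrv_cm3": [r.nrv_number for r in reports],
            "nrv_verdict": [verdict(r.exceeds_nrv) for r in reports],
        }
    )
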
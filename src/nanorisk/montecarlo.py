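"""Monte Carlo propagation of exposure-factor uncertainty.

Input variables are described by parametric distributions — lognormal for
airborne concentrations (right-skewed), uniform for physiological factors
(body weight, inhalation rate), triangular for behavioural factors
(exposure time/frequency/duration) and point for constants.  A simulation
draws all inputs jointly and independently, pushes each draw through the
deterministic exposure → dose → risk chain, and summarises each output with
mean, SD, median and 95th percentile.  10,000 iterations is the default,
which stabilises the output percentiles for these smooth chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateFitError,
    InsufficientDataError,
    InvalidInputError,
    InvalidSpecError,
)

#: Iteration count at which output percentiles are convergent for this model.
DEFAULT_ITERATIONS = 10_000

#: Default seed recorded in outputs for provenance.
DEFAULT_SEED = 20260326


@dataclass(frozen=True)
class DistributionSpec:
    """A named parametric distribution with a sampling contract.

    Families and parameters:

    ``lognormal``
        ``gm`` (geometric mean, > 0) and ``gsd`` (geometric SD, >= 1); or
        equivalently ``mu``/``sigma`` on the log scale.
    ``uniform``
        ``low`` <= ``high``.
    ``triangular``
        ``minimum`` <= ``mode`` <= ``maximum``.
    ``point``
        ``value`` (degenerate distribution).
    """

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = self.params
        if self.family == "lognormal":
            if "gm" in p:
                if p["gm"] <= 0 or p.get("gsd", 1.0) < 1.0:
                    raise InvalidSpecError("lognormal needs gm > 0 and gsd >= 1")
            elif "mu" in p:
                if p.get("sigma", 0.0) < 0:
                    raise InvalidSpecError("lognormal sigma must be >= 0")
            else:
                raise InvalidSpecError("lognormal needs gm/gsd or mu/sigma")
        elif self.family == "uniform":
            if p["low"] > p["high"]:
                raise InvalidSpecError("uniform needs low <= high")
        elif self.family == "triangular":
            if not (p["minimum"] <= p["mode"] <= p["maximum"]):
                raise InvalidSpecError("triangular needs min <= mode <= max")
        elif self.family == "point":
            if "value" not in p:
                raise InvalidSpecError("point needs a value")
        else:
            raise InvalidSpecError(f"unknown family {self.family!r}")

    # -- constructors -------------------------------------------------------
    @classmethod
    def lognormal(cls, gm: float, gsd: float) -> "DistributionSpec":
        return cls("lognormal", {"gm": float(gm), "gsd": float(gsd)})

    @classmethod
    def lognormal_logspace(cls, mu: float, sigma: float) -> "DistributionSpec":
        return cls("lognormal", {"mu": float(mu), "sigma": float(sigma)})

    @classmethod
    def uniform(cls, low: float, high: float) -> "DistributionSpec":
        return cls("uniform", {"low": float(low), "high": float(high)})

    @classmethod
    def uniform_pm(cls, centre: float, half_width: float) -> "DistributionSpec":
        """Uniform given as centre +/- half-width (how factor tables print it)."""
        return cls.uniform(centre - half_width, centre + half_width)

    @classmethod
    def triangular(cls, minimum: float, mode: float, maximum: float) -> "DistributionSpec":
        return cls("triangular",
                   {"minimum": float(minimum), "mode": float(mode), "maximum": float(maximum)})

    @classmethod
    def point(cls, value: float) -> "DistributionSpec":
        return cls("point", {"value": float(value)})

    # -- moments ------------------------------------------------------------
    @property
    def log_params(self) -> tuple[float, float]:
        """(mu, sigma) on the natural-log scale (lognormal only)."""
        p = self.params
        if "gm" in p:
            return np.log(p["gm"]), np.log(p["gsd"])
        return p["mu"], p["sigma"]

    def mean(self) -> float:
        p = self.params
        if self.family == "point":
            return p["value"]
        if self.family == "uniform":
            return 0.5 * (p["low"] + p["high"])
        if self.family == "triangular":
            return (p["minimum"] + p["mode"] + p["maximum"]) / 3.0
        mu, sigma = self.log_params
        return float(np.exp(mu + 0.5 * sigma**2))

    def median(self) -> float:
        p = self.params
        if self.family == "point":
            return p["value"]
        if self.family == "uniform":
            return 0.5 * (p["low"] + p["high"])
        if self.family == "triangular":
            lo, m, hi = p["minimum"], p["mode"], p["maximum"]
            if hi == lo:
                return lo
            c = (m - lo) / (hi - lo)
            if c >= 0.5:
                return lo + np.sqrt(0.5 * (hi - lo) * (m - lo))
            return hi - np.sqrt(0.5 * (hi - lo) * (hi - m))
        mu, _ = self.log_params
        return float(np.exp(mu))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 1:
            raise InvalidSpecError("n must be >= 1")
        p = self.params
        if self.family == "point":
            return np.full(n, p["value"])
        if self.family == "uniform":
            if p["low"] == p["high"]:
                return np.full(n, p["low"])
            return rng.uniform(p["low"], p["high"], size=n)
        if self.family == "triangular":
            if p["minimum"] == p["maximum"]:
                return np.full(n, p["mode"])
            return rng.triangular(p["minimum"], p["mode"], p["maximum"], size=n)
        mu, sigma = self.log_params
        return np.exp(rng.normal(mu, sigma, size=n))


def sample(spec: DistributionSpec, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` values from ``spec``, reproducibly for a given seed."""
    return spec.sample(n, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Lognormal fitting with goodness-of-fit diagnostics
# ---------------------------------------------------------------------------

@dataclass
class LognormalFit:
    spec: DistributionSpec
    mu: float
    sigma: float
    loglik: float
    aic: float
    chi_square: float
    chi_square_dof: int


def _aic(loglik: float, k: int) -> float:
    return 2 * k - 2 * loglik


def fit_lognormal(data, n_bins: int = 10, min_n: int = 8) -> LognormalFit:
    """Maximum-likelihood lognormal fit with AIC and chi-square diagnostics.

    The chi-square statistic uses ``n_bins`` equal-probability bins of the
    fitted distribution (expected count ``n / n_bins`` each); AIC counts
    ``k = 2`` parameters (log-mean and log-SD).
    """
    x = np.asarray(data, dtype=float)
    if x.size < min_n:
        raise InsufficientDataError(f"need >= {min_n} observations, got {x.size}")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise InvalidInputError("lognormal data must be positive and finite")
    logs = np.log(x)
    if np.ptp(logs) == 0.0:
        raise DegenerateFitError("all observations equal; lognormal scale is zero")
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))  # MLE
    loglik = float(np.sum(stats.lognorm.logpdf(x, s=sigma, scale=np.exp(mu))))
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = stats.lognorm.ppf(qs, s=sigma, scale=np.exp(mu))
    observed = np.histogram(x, bins=np.concatenate(([0.0], edges, [np.inf])))[0]
    expected = x.size / n_bins
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return LognormalFit(
        spec=DistributionSpec.lognormal_logspace(mu, sigma),
        mu=mu, sigma=sigma, loglik=loglik, aic=_aic(loglik, 2),
        chi_square=chi2, chi_square_dof=n_bins - 1 - 2,
    )


def uniform_fit_aic(data) -> float:
    """AIC of an ML uniform fit on the same data (model-selection comparator)."""
    x = np.asarray(data, dtype=float)
    width = x.max() - x.min()
    if width <= 0:
        raise DegenerateFitError("zero-width sample")
    return _aic(-x.size * float(np.log(width)), 2)


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

def percentile(samples: np.ndarray, q: float) -> float:
    """Percentile by linear interpolation between order statistics."""
    return float(np.percentile(samples, q, method="linear"))


@dataclass
class SimulationSummary:
    """Summary statistics of one simulated output."""

    name: str
    n_iterations: int
    seed: int
    mean: float
    sd: float
    p50: float
    p95: float
    samples: np.ndarray | None = None

    @classmethod
    def from_samples(cls, name: str, samples: np.ndarray, seed: int,
                     keep_samples: bool = True) -> "SimulationSummary":
        # constant samples (degenerate specs) collapse exactly: report the
        # common value, not the rounding noise of a summed variance
        if samples.size > 1 and np.ptp(samples) == 0.0:
            v = float(samples[0])
            return cls(name=name, n_iterations=samples.size, seed=seed,
                       mean=v, sd=0.0, p50=v, p95=v,
                       samples=samples if keep_samples else None)
        return cls(
            name=name,
            n_iterations=samples.size,
            seed=seed,
            mean=float(samples.mean()),
            sd=float(samples.std(ddof=1)) if samples.size > 1 else 0.0,
            p50=percentile(samples, 50),
            p95=percentile(samples, 95),
            samples=samples if keep_samples else None,
        )


def run_simulation(
    model: Callable[..., Mapping[str, float] | Mapping[str, np.ndarray]],
    specs: Mapping[str, DistributionSpec],
    n: int = DEFAULT_ITERATIONS,
    seed: int = DEFAULT_SEED,
    *,
    keep_samples: bool = True,
) -> tuple[dict[str, SimulationSummary], dict[str, np.ndarray]]:
    """Propagate ``specs`` through ``model`` by independent Monte Carlo.

    ``model`` is called once with one keyword array per spec (vectorised over
    the ``n`` joint draws) and must return a mapping of output name to array
    (or scalar broadcast over draws).  Sampling is simple independent Monte
    Carlo: no stratification and no input correlations.

    Returns the per-output summaries and the raw input draw matrix (for
    downstream sensitivity analysis).
    """
    if not specs:
        raise ConfigurationError("no input specs bound")
    rng = np.random.default_rng(seed)
    draws = {name: spec.sample(n, rng) for name, spec in specs.items()}
    try:
        outputs = model(**draws)
    except TypeError as exc:
        raise ConfigurationError(f"model inputs do not match specs: {exc}") from exc
    summaries = {}
    for out_name, values in outputs.items():
        arr = np.broadcast_to(np.asarray(values, dtype=float), (n,)).copy()
        summaries[out_name] = SimulationSummary.from_samples(
            out_name, arr, seed, keep_samples=keep_samples
        )
    return summaries, draws
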
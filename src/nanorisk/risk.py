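"""Margin-of-exposure and hazard-quotient risk characterisation.

MoE = POD / CDI_adj: below 100 flags possible risk for non-carcinogenic
endpoints; genotoxic carcinogens require MoE >= 10,000 for low concern.
HQ = adjusted air concentration / reference concentration (Rfc): above 1
flags non-cancer risk.  Materials without an Rfc (gold, graphene) get no
HQ — the quotient is reported as absent, not zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DivisionDomainError, InvalidPodError, UnavailableBenchmarkError

#: MoE below this flags possible risk for non-carcinogens.
MOE_NONCARCINOGEN_THRESHOLD = 100.0

#: MoE at or above this is low concern for genotoxic carcinogens.
MOE_GENOTOXIC_THRESHOLD = 10_000.0

#: HQ above this flags non-cancer risk.
HQ_THRESHOLD = 1.0

EndpointType = Literal["non_carcinogen", "genotoxic_carcinogen"]


def margin_of_exposure(pod, cdi_adj):
    """MoE = POD / CDI_adj (unitless); vectorised over arrays."""
    pod, cdi_adj = np.asarray(pod), np.asarray(cdi_adj)
    if np.any(pod <= 0):
        raise InvalidPodError("POD must be positive")
    if np.any(cdi_adj <= 0):
        raise DivisionDomainError("CDI_adj must be positive")
    out = pod / cdi_adj
    return float(out) if out.ndim == 0 else out


def hazard_quotient(c_air_adj, rfc):
    """HQ = adjusted air concentration / Rfc (unitless); vectorised.

    Raises :class:`UnavailableBenchmarkError` when no Rfc exists for the
    material, mirroring published tables that leave HQ blank in that case.
    """
    if rfc is None:
        raise UnavailableBenchmarkError("no reference concentration for this material")
    c_air_adj, rfc = np.asarray(c_air_adj), np.asarray(rfc)
    if np.any(rfc <= 0):
        raise UnavailableBenchmarkError("Rfc must be positive")
    if np.any(c_air_adj < 0):
        raise DivisionDomainError("adjusted concentration must be non-negative")
    out = c_air_adj / rfc
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RiskResult:
    """Risk values with their categorical verdicts."""

    moe: float
    moe_category: Literal["high_risk", "low_risk"]
    endpoint_type: EndpointType
    hq: float | None = None
    hq_category: Literal["low", "high"] | None = None


def classify(
    moe: float,
    hq: float | None = None,
    endpoint_type: EndpointType = "non_carcinogen",
) -> RiskResult:
    """Map MoE (and optionally HQ) to categorical risk verdicts.

    Boundary convention: MoE exactly at the threshold (100 non-carcinogen,
    10,000 genotoxic) is low risk; HQ exactly 1 is low (high requires > 1).
    """
    if moe < 0:
        raise InvalidPodError("MoE must be non-negative")
    threshold = (MOE_GENOTOXIC_THRESHOLD
                 if endpoint_type == "genotoxic_carcinogen"
                 else MOE_NONCARCINOGEN_THRESHOLD)
    moe_category = "low_risk" if moe >= threshold else "high_risk"
    hq_category = None
    if hq is not None:
        hq_category = "high" if hq > HQ_THRESHOLD else "low"
    return RiskResult(moe=moe, moe_category=moe_category,
                      endpoint_type=endpoint_type, hq=hq, hq_category=hq_category)
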
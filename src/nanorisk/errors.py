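"""Exception taxonomy for the risk-assessment pipeline.

Every stage raises a subclass of :class:`NanoriskError` so that the CLI can
label failures with the stage they came from.
"""


class NanoriskError(Exception):
    """Base class for all package errors."""


class InvalidGridError(NanoriskError):
    """Size-bin edges are non-increasing, non-positive, or otherwise malformed."""


class EmptyInputError(NanoriskError):
    """An operation received a series or array with no observations."""


class IncompatibleGridsError(NanoriskError):
    """Two binned series do not share the same size grid."""


class InvalidInputError(NanoriskError):
    """A numeric input violates its domain (e.g. negative concentration)."""


class InvalidDurationError(NanoriskError):
    """Session duration outside (0, 480] minutes."""


class InvalidFactorError(NanoriskError):
    """An exposure factor violates its physical bound (ET > 24 h/day, EF > 365 d/yr)."""


class DivisionDomainError(NanoriskError):
    """A denominator (body weight, averaging time, life expectancy) is zero."""


class InvalidPodError(NanoriskError):
    """Point of departure is non-positive."""


class UnavailableBenchmarkError(NanoriskError):
    """No reference concentration (Rfc) exists for the material, so HQ is undefined."""


class InvalidSpecError(NanoriskError):
    """Distribution parameters violate the family's constraints."""


class InsufficientDataError(NanoriskError):
    """Too few observations to fit a distribution."""


class DegenerateFitError(NanoriskError):
    """All observations equal: the lognormal scale parameter collapses to zero."""


class ConfigurationError(NanoriskError):
    """A simulation symbol is unbound or a run configuration is inconsistent."""


class UndefinedSensitivityError(NanoriskError):
    """Sensitivity analysis requested on a constant output."""
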
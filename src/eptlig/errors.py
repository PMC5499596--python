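"""Exception hierarchy for eptlig.

All package errors derive from :class:`EptligError` so callers can catch
everything with one clause; numerically flavoured errors also derive from
``ValueError`` to behave well in generic scientific code.
"""


class EptligError(Exception):
    """Base class for all eptlig errors."""


class DomainError(EptligError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class AlphabetError(EptligError, ValueError):
    """A sequence contains characters outside the declared alphabet."""


class ComplementarityError(EptligError, ValueError):
    """Probe and template are not complementary where they must be.

    Carries the 0-based ``position`` of the first offending base on the
    probe, when known.
    """

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class NonIdentifiabilityError(EptligError, ValueError):
    """The data cannot constrain the requested parameters (e.g. a melting
    curve that never melts)."""


class ConvergenceError(EptligError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class RangeError(EptligError, ValueError):
    """A root or solution does not exist in the allowed range."""


class InsufficientDataError(EptligError, ValueError):
    """Too few usable data points for an estimator."""


class UndefinedYieldError(EptligError, ValueError):
    """Yield cannot be computed (e.g. both band intensities are zero)."""


class ConfigurationError(EptligError, ValueError):
    """A system description is incomplete or inconsistent."""


class ParseError(EptligError, ValueError):
    """A data file violates its expected schema.

    ``location`` is a human-readable pointer (file and row) when available.
    """

    def __init__(self, message: str, location: str | None = None):
        super().__init__(message if location is None else f"{message} [{location}]")
        self.location = location
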
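"""Exception hierarchy.

Every error raised on purpose by the package derives from :class:`SitarError`,
so callers can catch one type at a pipeline boundary while tests can assert
the specific failure mode.
"""


class SitarError(Exception):
    """Base class for all package errors."""


class FormatError(SitarError):
    """Structural problem with an input file (missing column, no header...)."""


class ParseError(SitarError):
    """A cell could not be parsed; carries the offending row number."""


class RecordValidationError(SitarError):
    """A record violates a domain invariant (age/stature bounds, non-finite)."""


class DuplicateAgeError(SitarError):
    """Two measurements of one subject share the same recorded age."""


class ConfigurationError(SitarError):
    """Invalid configuration value (df too small, bad interval, bad factor...)."""


class CalibrationError(SitarError):
    """Reference-curve calibration failed; carries the residuals."""


class ConvergenceError(SitarError):
    """Optimiser failed to converge; carries the trace."""


class ContractError(SitarError):
    """A precondition between pipeline stages was violated."""


class LandmarkNotFoundError(SitarError):
    """No interior extremum of the velocity curve inside the search window."""


class LandmarkInstabilityError(SitarError):
    """Too large a share of posterior draws failed the landmark search."""


class DegenerateDistributionError(SitarError):
    """A sample is constant where spread is required (KDE, classification)."""
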
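"""Exception hierarchy.

All input/contract violations raise subclasses of :class:`C14GrowthError`
so callers can catch package errors without masking programming mistakes.
"""


class C14GrowthError(Exception):
    """Base class for all package errors."""


class ParseError(C14GrowthError, ValueError):
    """A text input could not be parsed; the message names the line."""


class DomainError(C14GrowthError, ValueError):
    """A value lies outside the mathematical domain of an operation."""


class GridError(C14GrowthError, ValueError):
    """Calendar grids that must match do not."""


class ConfigError(C14GrowthError, ValueError):
    """A configuration object is incomplete or inconsistent."""


class InsufficientDataError(C14GrowthError, ValueError):
    """Too few data points to carry out the computation."""


class DegenerateSupportError(C14GrowthError, ValueError):
    """Every probability mass underflowed to zero on the requested grid."""


class InitializationError(C14GrowthError, RuntimeError):
    """The sampler could not find a starting point with finite posterior."""


class UndefinedESSError(C14GrowthError, ValueError):
    """Effective sample size is undefined (e.g. constant chain)."""
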
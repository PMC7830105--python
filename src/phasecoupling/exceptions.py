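"""Exception hierarchy.

All package errors derive from :class:`PhaseCouplingError` so callers can
catch everything with one clause; the subclasses distinguish bad user
configuration from malformed files and from mathematically degenerate input.
"""


class PhaseCouplingError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(PhaseCouplingError, ValueError):
    """A required setting is missing or inconsistent (e.g. no sampling rate)."""


class FormatError(PhaseCouplingError, ValueError):
    """An input file does not conform to the expected layout."""


class ValidationError(PhaseCouplingError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(PhaseCouplingError, ValueError):
    """Input is formally valid but mathematically degenerate (constant signal,
    zero-norm grid, undefined direction)."""
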
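"""Exception hierarchy for tremorkit.

All exceptions derive from :class:`TremorKitError` so callers can catch any
package error with a single ``except`` clause.  The ``ValueError`` mix-in
keeps the functions usable with generic numeric code that expects standard
exceptions for bad inputs.
"""


class TremorKitError(Exception):
    """Base class for all tremorkit errors."""


class ValidationError(TremorKitError, ValueError):
    """An input violates a documented precondition (bad values, bad shape)."""


class ConfigurationError(TremorKitError, ValueError):
    """A run or generator configuration is inconsistent or empty."""


class InsufficientDataError(TremorKitError, ValueError):
    """A signal is too short for the requested computation."""


class NoOscillationError(TremorKitError, ValueError):
    """A signal carries no detectable oscillation (flat or constant input)."""
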
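"""Exception hierarchy.

Every error raised by spiba derives from :class:`SpibaError` so callers can
catch the whole family; subclasses distinguish bad inputs from degenerate
statistical situations (which may be data problems rather than caller bugs).
"""


class SpibaError(Exception):
    """Base class for all spiba errors."""


class InvalidInputError(SpibaError, ValueError):
    """Input violates a documented precondition."""


class InsufficientDataError(SpibaError):
    """Not enough samples/beats/spikes to run the requested computation."""


class DegenerateFitError(SpibaError):
    """A distribution fit is undefined (e.g. zero-variance sample)."""


class DegenerateWindowError(SpibaError):
    """A min-to-min normalization window has an undefined ratio."""


class ConfigurationError(SpibaError):
    """Parameter combination is infeasible (e.g. filter band beyond Nyquist)."""


class SchemaError(SpibaError):
    """A file does not match the expected column schema."""
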
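"""Exception hierarchy for rotometry.

All package-specific failures derive from :class:`RotometryError` so callers
can catch one base class at pipeline boundaries.
"""


class RotometryError(Exception):
    """Base class for all rotometry errors."""


class SchemaError(RotometryError):
    """Input table or row set violates the expected schema."""


class RangeError(RotometryError):
    """A coordinate lies outside the normalized [0, 1] image square."""


class DegenerateGeometryError(RotometryError):
    """A geometric computation is undefined (zero-length segment, etc.)."""


class OutOfFrameError(RotometryError):
    """A projected landmark falls outside the image frame."""


class ConfigError(RotometryError):
    """A configuration object or file is invalid."""


class SplitError(RotometryError):
    """A train/test split cannot be constructed as requested."""


class UnsupportedModelError(RotometryError):
    """An operation was requested for a model type it does not support."""
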
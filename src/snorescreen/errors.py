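"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`SnoreScreenError`, so callers (and the CLI) can distinguish
user/data errors from genuine bugs.
"""


class SnoreScreenError(Exception):
    """Base class for all errors raised by snorescreen."""


class ParameterError(SnoreScreenError, ValueError):
    """A parameter value is outside its documented domain."""


class InputSizeError(SnoreScreenError, ValueError):
    """An input is too short / too small for the requested operation."""


class FormatError(SnoreScreenError, ValueError):
    """A file could not be parsed in the expected format."""


class DimensionError(SnoreScreenError, ValueError):
    """Array shapes are inconsistent with each other or with a config."""


class DegenerateFrameError(SnoreScreenError, ValueError):
    """A frame is all-zero (or otherwise unusable) for model fitting."""


class DataError(SnoreScreenError, ValueError):
    """A dataset violates a precondition (e.g. a single-class training set)."""


class ConfigError(SnoreScreenError, ValueError):
    """A model or pipeline configuration is internally inconsistent."""
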
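"""Exception hierarchy.

Errors are split into configuration problems (bad user input before any
computation), data problems (bad values inside otherwise valid containers),
and schema problems (tables or models that do not line up with each other).
"""


class GbmsurvError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GbmsurvError):
    """Invalid simulation or pipeline configuration."""


class DataError(GbmsurvError):
    """Non-finite, non-positive or otherwise invalid data values."""


class ShapeError(DataError):
    """Array dimensions incompatible with the requested operation."""


class SchemaError(GbmsurvError):
    """Tables, labels or models that do not match each other."""


class StratificationError(GbmsurvError):
    """Too few subjects per class for the requested fold structure."""


class DegenerateDataError(DataError):
    """Input degenerate for the operation (e.g. all code units pruned)."""
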
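"""Exception hierarchy shared by all pipeline stages.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
AnalysisError -> 4.
"""


class VasculensError(Exception):
    """Base class for all package errors."""


class ConfigError(VasculensError):
    """Invalid or incomplete run configuration."""


class DataError(VasculensError):
    """Problem with input data files or their metadata."""


class FormatError(DataError):
    """File content does not match the expected format."""


class MetadataError(DataError):
    """Required metadata (timestamps, pixel size) missing or inconsistent."""


class AnalysisError(VasculensError):
    """An analysis stage received inputs it cannot process."""


class DegenerateInputError(AnalysisError):
    """Input carries no usable signal (e.g. constant image)."""


class MaskConflictError(AnalysisError):
    """Manual correction masks contradict each other."""
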
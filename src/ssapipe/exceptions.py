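"""Exception hierarchy shared across the pipeline.

ConfigError maps to CLI exit code 2, DataError (and subclasses) to exit code 3.
"""


class SsaPipeError(Exception):
    """Base class for all package errors."""


class ConfigError(SsaPipeError):
    """Invalid configuration file or parameter value."""


class DataError(SsaPipeError):
    """Input data violates a precondition (missing frames, bad baseline, ...)."""


class InsufficientDataError(DataError):
    """Not enough frames / trials / subjects for the requested operation."""


class DegenerateDataError(DataError):
    """Sample is degenerate for the requested statistic (constant vector, ...)."""
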
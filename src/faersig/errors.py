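"""Error hierarchy shared across the pipeline.

Configuration problems (a bad parameter value, an unknown method name) are
distinguished from data problems (a missing table, an empty background) so the
command-line layer can map them to distinct exit codes.
"""


class FaersigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FaersigError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DataError(FaersigError, RuntimeError):
    """Input data cannot be processed (missing table, empty background, ...)."""
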
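"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError (and its
subclass FormatError) -> 3.
"""


class AcidepError(Exception):
    """Base class for all package errors."""


class ConfigError(AcidepError):
    """Invalid configuration: bad parameter value, missing metadata."""


class DataError(AcidepError):
    """Input data violates a precondition (missing condition, empty map...)."""


class FormatError(DataError):
    """A file could not be parsed: malformed header, duplicate ids,
    unparseable numeric cells."""
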
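"""Exception hierarchy shared across pipeline stages.

Exit-code mapping for the CLI: ConfigurationError -> 2,
DataValidationError -> 3, MissingArtifactError -> 4.
"""


class NcxtalkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NcxtalkError):
    """A parameter, column map, or config file is invalid."""


class DataValidationError(NcxtalkError):
    """An input table violates a documented invariant."""


class PipelineStateError(NcxtalkError):
    """An operation was called before its prerequisite stage."""


class MissingArtifactError(NcxtalkError):
    """A required upstream artifact does not exist on disk."""
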
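"""Exception hierarchy used across the pipeline."""


class EegDfcError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EegDfcError):
    """A configuration value violates an invariant (names the offending field)."""


class DataError(EegDfcError):
    """Input data violates an operation's precondition."""


class DependencyError(EegDfcError):
    """An optional runtime dependency (e.g. a pretrained backbone) is missing."""
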
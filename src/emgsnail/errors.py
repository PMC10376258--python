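"""Exception hierarchy shared by all pipeline stages."""


class EmgSnailError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EmgSnailError):
    """Invalid or inconsistent configuration values."""


class FormatError(EmgSnailError):
    """Malformed input file (names the offending line/field where possible)."""


class DegenerateSignalError(EmgSnailError):
    """Signal too short, constant, or otherwise unusable for an operation."""


class ProtocolError(EmgSnailError):
    """Evaluation-protocol violation (too few subjects, empty inputs, ...)."""


class RegistryError(EmgSnailError):
    """Feature-registry violation (unknown or duplicate feature name)."""


class SearchExhausted(EmgSnailError):
    """Raised when a search cannot propose any further candidate."""
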
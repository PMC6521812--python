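"""Exception types shared across the pipeline."""


class PupilError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PupilError):
    """Invalid paradigm or pipeline configuration."""


class FormatError(PupilError):
    """Malformed recording or screening file; message names the offending line."""


class ValidationError(PupilError):
    """Input data violates a documented precondition."""
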
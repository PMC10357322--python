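"""Exception hierarchy shared across the package."""


class OralsaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OralsaError):
    """A file does not conform to the expected on-disk schema."""


class ValidationError(OralsaError):
    """Parsed data violates a domain invariant."""


class ConfigError(OralsaError):
    """A simulation or pipeline configuration is internally inconsistent."""


class AnalysisError(OralsaError):
    """An analysis was requested on data for which it is undefined."""
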
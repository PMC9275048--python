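"""Exception hierarchy shared across the package."""


class DeggnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DeggnetError, ValueError):
    """A file does not conform to its declared external format."""


class ParseError(FormatError):
    """A cell or line could not be parsed; message names the location."""


class ValidationError(DeggnetError, ValueError):
    """Input data violates a documented precondition or invariant."""


class RankDeficiencyError(ValidationError):
    """A regression design matrix is rank deficient; message names the columns."""


class ConfigError(DeggnetError, ValueError):
    """A pipeline configuration is invalid."""
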
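"""Exception hierarchy shared across the package."""


class CodepnetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CodepnetError, ValueError):
    """Invalid argument, configuration value or degenerate input."""


class FormatError(CodepnetError, ValueError):
    """Malformed external file (bad cell, short GMT line, ...)."""


class IntegrityError(CodepnetError, ValueError):
    """Internally inconsistent data (duplicate identifiers, shape mismatch)."""
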
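"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: parse/I-O problems exit 1,
validation/configuration problems exit 2.
"""


class APCpredError(Exception):
    """Base class for all package errors."""


class ParseError(APCpredError):
    """A file could not be parsed (malformed FASTA/TSV)."""


class ValidationError(APCpredError):
    """An input violated a documented contract."""


class ConfigError(ValidationError):
    """A configuration value is invalid or produces a degenerate result."""


class ResourceError(APCpredError):
    """A sampling or generation request could not be satisfied."""


class WindowRejection(APCpredError):
    """An epitope could not be standardized to the requested window."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class ModelFormatError(APCpredError):
    """A model archive is missing required blocks or is version-incompatible."""
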
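"""Exception hierarchy for acpstack.

All package-specific failures derive from :class:`AcpstackError` so callers
(and the CLI) can distinguish data problems from genuine bugs.
"""


class AcpstackError(Exception):
    """Base class for all acpstack errors."""


class ValidationError(AcpstackError):
    """Input data violates a documented contract (alphabet, length, labels)."""


class FastaParseError(ValidationError):
    """A FASTA file is structurally malformed."""


class ConfigError(AcpstackError):
    """A configuration object violates its invariants."""


class TrainingError(AcpstackError):
    """Model training cannot proceed (missing class, empty feature selection)."""


class ModelFormatError(AcpstackError):
    """A model archive is unreadable, truncated, or schema-incompatible."""
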
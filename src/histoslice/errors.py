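"""Exception hierarchy.

``DegenerateInputError`` maps to CLI exit code 2; everything else is a
plain failure (exit code 1).
"""


class HistosliceError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HistosliceError):
    """Invalid chain/domain/parameter configuration (e.g. dimensionality
    mismatch between consecutive chain members)."""


class DegenerateInputError(HistosliceError):
    """Inputs that make the requested registration meaningless (empty
    overlap, missing photos, prior outside the field of view...)."""


class SerialisationError(HistosliceError):
    """Chain file version mismatch, truncation or corruption."""


class NotInvertibleError(HistosliceError):
    """A chain member required for backward mapping has no inverse."""
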
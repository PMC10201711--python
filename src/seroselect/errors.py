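"""Exception hierarchy for seroselect."""


class SeroselectError(Exception):
    """Base class for all package-specific errors."""


class BindingValidationError(SeroselectError, ValueError):
    """Raised when binding data fail structural validation (negative,
    non-finite or non-numeric RFU, duplicate identifiers, malformed
    columns)."""


class ConfigError(SeroselectError, ValueError):
    """Raised for invalid configuration values or unknown contrast names."""


class EmptyGroupError(SeroselectError, ValueError):
    """Raised when cohort filtering empties one pole of a contrast."""


class DegenerateTableError(SeroselectError, ValueError):
    """Raised for an all-zero 2x2 contingency table."""


class EmptyModelError(SeroselectError, ValueError):
    """Raised when stability selection retains no peptide."""


class AlignmentError(SeroselectError, KeyError):
    """Raised when peptide or sample identifiers cannot be aligned
    between a positivity matrix and a contrast model."""
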
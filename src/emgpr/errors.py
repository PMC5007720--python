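"""Exception hierarchy.

Errors are split by what went wrong, not where: structural problems with a
container (missing fields), bad data values (non-finite samples, dimension
mismatches), invalid user configuration, and numeric failures during fitting.
"""


class EmgprError(Exception):
    """Base class for all package errors."""


class StructuralError(EmgprError):
    """A container is missing a required field or has the wrong layout."""


class DataError(EmgprError):
    """Data values violate an invariant (non-finite, inconsistent shape)."""


class ConfigurationError(EmgprError):
    """A user-supplied configuration value is invalid or infeasible."""


class NumericError(EmgprError):
    """A numeric computation failed (singular matrix, diverging error)."""
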
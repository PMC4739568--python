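"""Exception hierarchy shared by all divestate modules."""


class DivestateError(Exception):
    """Base class for all package errors."""


class FormatError(DivestateError):
    """A file does not match the expected layout (e.g. missing column)."""


class DataError(DivestateError):
    """Well-formed file whose contents violate a data invariant."""


class ContractError(DivestateError):
    """A caller violated an operation precondition (lengths, emptiness...)."""


class DomainError(DivestateError):
    """Numeric input outside the valid domain of a formula."""


class CalibrationError(DivestateError):
    """Device-orientation calibration could not be performed."""


class StandardizationError(DivestateError):
    """A channel cannot be standardized (zero variance)."""


class FitError(DivestateError):
    """Mixture fitting failed on every restart."""


class DesignError(DivestateError):
    """An analysis run design is infeasible for the supplied data."""


class ConfigError(DivestateError):
    """A configuration or scenario violates its invariants."""
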
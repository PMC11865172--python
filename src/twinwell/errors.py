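"""Exception hierarchy shared across modules."""


class TwinwellError(Exception):
    """Base class for all package errors."""


class SchemaError(TwinwellError):
    """Input table is missing required columns or has a malformed header."""


class IntegrityError(TwinwellError):
    """Rows violate cohort invariants (duplicates, discordant pairs, bad codes)."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report or []


class ValidationError(TwinwellError):
    """A value is outside its declared domain."""


class UndefinedStatisticError(TwinwellError):
    """A statistic is undefined for the given input (e.g. alpha with <2 items)."""


class FitError(TwinwellError):
    """Model fitting failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateDesignError(TwinwellError):
    """Design matrix is rank deficient (e.g. no within-pair exposure variance)."""


class ComparabilityError(TwinwellError):
    """Models being compared were not fitted to identical case sets."""


class ConfigError(TwinwellError):
    """A simulation or run configuration is infeasible or malformed."""
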
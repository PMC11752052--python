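"""Exception hierarchy.

CLI exit codes: 0 success, 2 schema/config, 3 convergence, 4 coverage.
"""


class ArmCompareError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(ArmCompareError):
    """Input table violates the expected schema (bad enum value, bad type)."""

    exit_code = 2


class DuplicateError(SchemaError):
    """Duplicate study or (study, arm) identifier."""


class ScaleLookupError(SchemaError):
    """An arm references a scale name absent from the scale registry."""


class ConfigError(ArmCompareError):
    """Unknown filter criterion or malformed analysis configuration."""

    exit_code = 2


class DomainError(ArmCompareError):
    """A numeric argument outside its mathematically valid domain."""

    exit_code = 2


class ImputationError(ArmCompareError):
    """No applicable rule to recover a missing dispersion statistic."""

    exit_code = 2


class ConvergenceError(ArmCompareError):
    """Variance-component optimization failed to converge."""

    exit_code = 3


class CoverageError(ArmCompareError):
    """Required field missing for too many records to run an analysis."""

    exit_code = 4


class DesignError(ArmCompareError):
    """Rank-deficient moderator design matrix."""

    exit_code = 2


class ContrastError(ArmCompareError):
    """Requested contrast involves a coefficient absent from the fit."""

    exit_code = 2
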
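"""Exception hierarchy.

Two broad families matter for CLI exit codes: problems with the user's
input (:class:`ValidationError`, exit code 2) and problems arising during
computation on valid input (:class:`ComputationError`, exit code 3).
"""


class StratCRTError(Exception):
    """Base class for all package errors."""


class ValidationError(StratCRTError):
    """Malformed or inconsistent input data or configuration."""


class RecordValidationError(ValidationError):
    """A prescription record is missing or has an unparseable field."""

    def __init__(self, record_id: str, field: str, message: str = ""):
        self.record_id = record_id
        self.field = field
        detail = f": {message}" if message else ""
        super().__init__(f"record {record_id!r}: invalid field {field!r}{detail}")


class ContractViolationError(StratCRTError):
    """An operation was called outside its stated preconditions."""


class ComputationError(StratCRTError):
    """A statistical computation could not be carried out."""


class DegenerateTableError(ComputationError):
    """A 2x2 table has a zero row or column margin."""


class UndefinedPercentageError(ComputationError):
    """Percentage requested with a zero denominator."""


class NoDetectableEffectError(ComputationError):
    """Sample-size calculation with pi1 == pi0."""


class SeparationError(ComputationError):
    """Logistic fit did not converge and a coefficient diverged."""

    def __init__(self, term: str, coef: float):
        self.term = term
        self.coef = coef
        super().__init__(
            f"separation suspected: term {term!r} diverged (coefficient {coef:.2f}, "
            "fit not converged)"
        )


class RankDeficiencyError(ComputationError):
    """Design matrix is rank deficient after encoding."""

    def __init__(self, aliased: list[str]):
        self.aliased = list(aliased)
        super().__init__(f"design matrix rank deficient; aliased terms: {self.aliased}")


class DegenerateWeightError(ComputationError):
    """A stratum has zero between-cluster variance; weights undefined."""


class SmallStratumError(ComputationError):
    """A stratum has fewer than 2 clusters in an arm."""
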
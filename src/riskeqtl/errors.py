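"""Exception hierarchy for the eQTL mapping pipeline."""


class RiskEqtlError(Exception):
    """Base class for all pipeline errors."""


class InvalidArgumentError(RiskEqtlError, ValueError):
    """An argument violates a documented precondition."""


class GenerationFailureError(RiskEqtlError):
    """The synthetic generator could not satisfy its contract.

    Carries enough context (offending SNP index, r-squared band, ...)
    to diagnose an infeasible configuration.
    """


class UndefinedStatisticError(RiskEqtlError):
    """A statistic is undefined for the given input (e.g. all-missing SNP)."""


class UndefinedLdError(UndefinedStatisticError):
    """LD is undefined because a dosage vector has zero variance."""


class UnknownSnpError(RiskEqtlError, KeyError):
    """A SNP id was not found in the genotype panel."""


class QcEmptyError(RiskEqtlError):
    """SNP quality control removed every marker."""


class FilterEmptyError(RiskEqtlError):
    """Expression filtering removed every gene."""


class CollinearityError(RiskEqtlError):
    """A design matrix is rank deficient; names the dependent columns."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class DecompositionError(RiskEqtlError):
    """A matrix decomposition failed (degenerate input)."""


class ConvergenceError(RiskEqtlError):
    """An iterative fit did not converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class NoPeakError(RiskEqtlError):
    """A gene has no significant association from which to pick a peak."""
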
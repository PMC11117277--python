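"""Exception hierarchy for the empyema analysis pipeline."""


class EmpyemaPBAError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EmpyemaPBAError, ValueError):
    """Invalid configuration value (probability outside [0,1], negative hazard, ...)."""


class ParseError(EmpyemaPBAError, ValueError):
    """Malformed raw-record file; the message names the offending row."""


class RecordValidationError(EmpyemaPBAError, ValueError):
    """Out-of-range raw value (Barthel > 100, negative lab, ...)."""


class ContractViolation(EmpyemaPBAError, RuntimeError):
    """An operation was called on input its precondition excludes."""


class SeparationError(EmpyemaPBAError, RuntimeError):
    """Perfect separation in the logistic propensity model."""


class CollinearityError(EmpyemaPBAError, RuntimeError):
    """Rank-deficient design matrix; the message names the covariate."""


class DegenerateScoreError(EmpyemaPBAError, RuntimeError):
    """Fitted propensity score numerically 0 or 1; IPTW weight undefined."""


class NoEventsError(EmpyemaPBAError, RuntimeError):
    """Cox fit requested for a cause with zero observed events."""


class DivergenceError(EmpyemaPBAError, RuntimeError):
    """Monotone partial likelihood / non-convergence of the Cox Newton iteration."""


class DegenerateFitError(EmpyemaPBAError, RuntimeError):
    """Singular information matrix in the sandwich variance."""


class UndefinedTestError(EmpyemaPBAError, ValueError):
    """Chi-squared test undefined (zero margin)."""


class SolverError(EmpyemaPBAError, RuntimeError):
    """Prior elicitation constraints infeasible."""


class IncompatibleParametersError(EmpyemaPBAError, ValueError):
    """Sampled bias parameters imply a probability above 1."""


class ArtifactMissingError(EmpyemaPBAError, FileNotFoundError):
    """A pipeline stage was invoked before its upstream stage produced its artifact."""
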
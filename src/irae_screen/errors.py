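"""Exception hierarchy.

Two broad classes matter for the CLI exit-code contract: malformed or
inconsistent inputs (exit 2) and statistics that are undefined or degenerate
on otherwise well-formed inputs (exit 3).
"""


class IraeScreenError(Exception):
    """Base class for all package errors."""


class InputError(IraeScreenError):
    """Malformed, missing or inconsistent input (CLI exit code 2)."""


class ConfigError(InputError):
    """Invalid simulation or pipeline configuration."""


class FeatureMissingError(InputError):
    """A requested gene/feature is absent from an expression matrix."""


class NestingError(InputError):
    """Likelihood-ratio test requested for a non-nested model pair."""


class DegenerateStatisticsError(IraeScreenError):
    """A statistic is undefined on this input (CLI exit code 3)."""


class DegenerateInputError(DegenerateStatisticsError):
    """Constant vectors, empty matrices, and similar degeneracies."""


class DegenerateGroupError(DegenerateStatisticsError):
    """A required comparison group is empty."""


class InsufficientGroupsError(DegenerateStatisticsError):
    """Too few strata (cancer types, grades) to form the statistic."""


class UndefinedStatisticError(DegenerateStatisticsError):
    """Zero cells make the odds ratio undefined and correction is off."""


class SingularDesignError(DegenerateStatisticsError):
    """Rank-deficient design matrix in a regression."""


class FoldFailureError(SingularDesignError):
    """A leave-one-out fold produced a singular refit."""


class ConvergenceError(DegenerateStatisticsError):
    """Iterative fit failed to converge (e.g. logistic separation)."""
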
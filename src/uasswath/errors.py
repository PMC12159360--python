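"""Exception hierarchy shared by all analysis modules."""


class UasswathError(ValueError):
    """Base class for all domain errors raised by this package."""


class ParameterError(UasswathError):
    """A generator or analysis parameter violates its precondition."""


class FormatError(UasswathError):
    """An input file or record does not match the expected schema."""


class DegenerateDesignError(UasswathError):
    """A regression design matrix is rank-deficient (e.g. constant x)."""


class UndefinedStatisticError(UasswathError):
    """A statistic is undefined for the given data (zero mean, zero control...)."""
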
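"""Exception types shared across the package."""


class AccessMarketError(Exception):
    """Base class for all package-specific errors."""


class DomainError(AccessMarketError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ValidationError(AccessMarketError, ValueError):
    """An input table or configuration fails schema or sanity checks."""


class ConvergenceError(AccessMarketError, RuntimeError):
    """An iterative solver failed to converge within its budget."""


class DegenerateMarketError(AccessMarketError, ValueError):
    """A market has no agents (or no positive endowments) on one side."""


class NoEquilibriumError(AccessMarketError, RuntimeError):
    """Growth and total-catch policy never cross on the tabulated range."""


class MultipleEquilibriaError(AccessMarketError, RuntimeError):
    """More than one stable growth/policy crossing; caller must disambiguate."""
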
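"""Exception types shared across the package."""


class HydrostomaError(Exception):
    """Base class for package errors."""


class FormatError(HydrostomaError):
    """A gas-exchange table is missing a mandatory column or is malformed."""


class EmptyInputError(HydrostomaError):
    """No records survived reading/filtering."""


class UnitError(HydrostomaError):
    """Unsupported unit tag or unit pair."""


class DomainError(HydrostomaError, ValueError):
    """An argument lies outside the physical domain of an operation."""


class SolverError(HydrostomaError):
    """The leaf solver failed to bracket or converge (should not occur for valid inputs)."""


class StagingError(HydrostomaError):
    """A pipeline stage ran before its prerequisites (e.g. GLB fit before OBS fit)."""
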
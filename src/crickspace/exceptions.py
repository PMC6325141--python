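"""Exception hierarchy shared across the package."""


class CrickSpaceError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CrickSpaceError, ValueError):
    """A rate, count or configuration value is outside its valid domain."""


class EmptyTableError(CrickSpaceError, ValueError):
    """An input table is empty, or filtering removed every gene."""


class DegenerateInputError(CrickSpaceError, ValueError):
    """An operation is undefined on this input (zero variance, collinearity...)."""


class InfeasibleSpecError(CrickSpaceError, ValueError):
    """A synthetic-data specification cannot be satisfied."""
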
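"""Exception hierarchy shared across the package."""


class FctfError(Exception):
    """Base class for all package errors."""


class ConfigError(FctfError):
    """Bad configuration: missing/unknown keys, unresolvable columns."""


class ValidationError(FctfError):
    """A row or value violates a domain invariant."""


class DialectError(FctfError):
    """An input table's dialect cannot be determined unambiguously."""


class ParameterError(FctfError):
    """An operation was called with an out-of-range parameter."""


class DegenerateMatrixError(FctfError):
    """Every criterion column is constant; entropy weights are undefined.

    Callers may recover by supplying equal weights explicitly.
    """


class ClassBalanceError(FctfError):
    """Fewer than two examples in one class; classifiers cannot be scored."""


class GenerationError(FctfError):
    """A synthetic-data spec produced no usable data."""


class StageError(FctfError):
    """A mandatory pipeline stage failed."""
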
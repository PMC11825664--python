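"""Exception hierarchy shared across the package.

Each class maps to a CLI exit code so scripted pipelines can distinguish
misuse from bad data from numerical failure.
"""


class NormevalError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class UsageError(NormevalError):
    """Invalid arguments, configuration, or call contract violation."""

    exit_code = 2


class ContractError(UsageError):
    """Inputs violate an operation's preconditions (e.g. shape mismatch)."""


class DataError(NormevalError):
    """Input data is malformed, inconsistent, or missing pieces."""

    exit_code = 3


class FormatError(DataError):
    """A file parsed but its content violates the declared format."""


class DegenerateInputError(DataError):
    """Input is valid in form but degenerate for the operation (e.g. an
    all-zero image whose normalization percentile is 0)."""


class NumericalError(NormevalError):
    """A numerical routine failed its stability check."""

    exit_code = 4
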
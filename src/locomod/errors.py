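"""Exception hierarchy shared by all locomod modules.

Three failure classes are distinguished because the CLI maps them to
distinct exit codes: bad parameters (caller error), bad data (input
violates a format or a scientific precondition), and insufficient data
(a dataset that is valid but too small to analyze, e.g. fewer than five
retained cycles).
"""


class LocomodError(Exception):
    """Base class for all locomod errors."""


class ParameterError(LocomodError, ValueError):
    """An argument or configuration value is invalid."""


class DataError(LocomodError, ValueError):
    """Input data violate a precondition (e.g. all-zero muscle channel)."""


class FormatError(DataError):
    """An on-disk file is malformed (ragged rows, non-numeric cells, ...)."""


class InsufficientDataError(DataError):
    """A dataset is valid but too small (fewer than five analyzable cycles)."""


#: CLI exit codes, one per failure class.
EXIT_PARAMETER = 2
EXIT_DATA = 3
EXIT_INSUFFICIENT = 4
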
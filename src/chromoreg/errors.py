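"""Exception taxonomy.

Exit-code mapping in the CLI: ValidationError/InputError/ConfigError -> 1,
anything else -> 2.
"""


class ChromoregError(Exception):
    """Base class for all package errors."""


class InputError(ChromoregError):
    """A file could not be read or is not in the expected format."""


class ValidationError(ChromoregError):
    """Input parsed but violates a contract (bad coordinates, missing gene...)."""


class ConfigError(ChromoregError):
    """Invalid parameters or an infeasible simulation request."""


class UndefinedStatisticError(ChromoregError):
    """A statistic is undefined for the given table (zero denominator)."""
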
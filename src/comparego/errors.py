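"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage/configuration problems (2),
data/parse problems (3), statistical precondition failures (4).
"""


class CompareGOError(Exception):
    """Base class for all package errors."""


class ConfigError(CompareGOError):
    """Invalid configuration or arguments (CLI exit code 2)."""


class DataError(CompareGOError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


class StatsError(CompareGOError):
    """A statistical precondition is not met (CLI exit code 4)."""
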
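"""Exception hierarchy shared across pipeline stages.

Exit-code mapping used by the CLI: config errors -> 2, data errors -> 3,
numeric failures -> 4.
"""


class HybridscopeError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(HybridscopeError):
    """Invalid configuration value or combination."""

    exit_code = 2


class DataError(HybridscopeError):
    """Malformed or inconsistent input data."""

    exit_code = 3


class NumericError(HybridscopeError):
    """Numerical failure (non-finite loss, degenerate statistic)."""

    exit_code = 4


class PlacementError(DataError):
    """Synthetic field too crowded to place all requested cells."""
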
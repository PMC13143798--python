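"""Exception hierarchy shared across the toolkit.

Exit codes (used by the CLI): 0 success, 2 configuration error,
3 data-format error, 4 numeric/fit error.
"""


class VolcapError(Exception):
    """Base class for all toolkit errors."""

    exit_code = 1


class ConfigError(VolcapError):
    """Invalid configuration value or unknown configuration key."""

    exit_code = 2


class FormatError(VolcapError):
    """Malformed input data (missing columns, unparseable fields, ...)."""

    exit_code = 3


class GridError(FormatError):
    """Timestamps do not lie on the expected uniform grid."""


class ContractError(VolcapError):
    """An operation was called outside its contract (e.g. a span crossing a
    phase boundary)."""

    exit_code = 4


class FitError(VolcapError):
    """A regression / fit could not be performed."""

    exit_code = 4


class InsufficientWindowError(FitError):
    """Too few samples inside the requested fit window."""

    def __init__(self, message: str, n_points: int = 0):
        super().__init__(message)
        self.n_points = n_points


class InsufficientGradientError(FitError):
    """No distinct steep region found (flat capnogram)."""


class InsufficientDataError(FitError):
    """Fewer observations than the statistic requires."""
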
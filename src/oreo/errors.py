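"""Exception hierarchy shared by all pipeline stages.

Exit codes (used by the CLI): 2 = usage (click), 3 = validation/config,
4 = I/O, 5 = undefined result (e.g. zero usable reads, zero off-target).
"""


class OreoError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class ConfigError(OreoError):
    """Invalid configuration or precondition violation."""

    exit_code = 3


class InputError(OreoError):
    """Missing/unreadable input, missing BAM index, reference mismatch."""

    exit_code = 4


class UndefinedResultError(OreoError):
    """A statistic whose denominator is empty or zero; never silently 0."""

    exit_code = 5


class GatingError(UndefinedResultError):
    """Gating impossible (empty control or no live events)."""
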
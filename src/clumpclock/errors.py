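"""Exception types shared across the package."""


class ClumpclockError(Exception):
    """Base class for package-specific errors."""


class ConfigError(ClumpclockError, ValueError):
    """Raised for unknown config keys or invariant violations in a config file."""


class DegenerateInputError(ClumpclockError, ValueError):
    """Raised when a statistic is undefined on its input.

    Examples: an event table with zero range in a channel, a constant time
    series, or a series with fewer than two detectable peaks.
    """


class EmptyPoolError(ClumpclockError, ValueError):
    """Raised when phenotype selection leaves a spore pool with no survivors."""
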
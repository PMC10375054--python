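"""Exception types shared across the package."""


class MitopopError(Exception):
    """Base class for package-specific errors."""


class InputError(MitopopError, ValueError):
    """Malformed, empty, or otherwise unusable input."""


class AlignmentError(InputError):
    """Sequences violate alignment invariants (e.g. unequal lengths)."""


class PopulationMapError(InputError):
    """Sample-to-population map is missing entries or malformed."""


class UndefinedStatisticError(MitopopError, ValueError):
    """A statistic is undefined for the given input (e.g. n < 2, no data)."""


class ConfigurationError(MitopopError, ValueError):
    """Invalid parameter or configuration values."""
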
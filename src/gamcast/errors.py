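"""Exception hierarchy shared across pipeline stages."""


class GamcastError(Exception):
    """Base class for all gamcast errors."""


class ConfigurationError(GamcastError):
    """Invalid configuration value (bad cadence, link name, fraction, grid …)."""


class DegenerateVariableError(GamcastError):
    """A variable is constant (or otherwise unusable) where variation is required."""


class DataSufficiencyError(GamcastError):
    """Not enough observations remain for the requested computation."""


class InterpolationError(GamcastError):
    """A series cannot be interpolated (single observation, no observed values)."""


class VariantError(GamcastError):
    """Derived-variant kind incompatible with the series cadence."""


class CoverageError(GamcastError):
    """A kernel evaluation point has no data in its window (grid must be trimmed)."""


class AlignmentError(GamcastError):
    """Two bands were compared on different evaluation grids."""


class SplitError(GamcastError):
    """Requested train/validation/test split does not fit the available periods."""


class TuningError(GamcastError):
    """Every hyperparameter configuration in the grid failed to fit."""
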
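"""Exception types shared across the package."""


class MotregressError(ValueError):
    """Base class for all package-specific errors."""


class InvalidConfigError(MotregressError):
    """A configuration object violates its invariants."""


class DegenerateDataError(MotregressError):
    """Input data is degenerate for the requested operation (e.g. empty
    mask, zero-variance artifact everywhere, all-zero graph)."""


class GridMismatchError(MotregressError):
    """Spatial grids or volume counts of bundled images disagree."""


class NumericalFailureError(MotregressError):
    """A numerical routine produced non-finite values."""
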
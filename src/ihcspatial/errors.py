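"""Exception hierarchy."""


class IHCSpatialError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(IHCSpatialError, ValueError):
    """A generator or render specification violates its invariants."""


class ConfigurationError(IHCSpatialError, ValueError):
    """A stain system or pipeline configuration is unusable."""


class DegenerateHistogramError(IHCSpatialError, ValueError):
    """Automatic thresholding was asked for on a (near-)constant image."""


class UndefinedStatisticError(IHCSpatialError, ValueError):
    """A spatial statistic was requested on a pattern too small to define it."""


class ShapeMismatchError(IHCSpatialError, ValueError):
    """Two rasters that must share a shape do not."""
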
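"""Exception hierarchy for lastfit."""


class LastfitError(Exception):
    """Base class for all lastfit errors."""


class GridError(LastfitError):
    """Invalid surface grid (shape, coordinates, non-finite heights)."""


class DegenerateGeometryError(LastfitError):
    """Zero-length segment, zero contour extent, or similar degeneracy."""


class DivisionHazardError(LastfitError):
    """A height that appears in a denominator is zero (or numerically so)."""


class FieldOfViewError(LastfitError):
    """Camera geometry places the laser stripe off the sensor."""


class NoPeakError(LastfitError):
    """Intensity window contains no interior maximum."""


class NoLineError(LastfitError):
    """No laser stripe found in the image column profile."""


class CalibrationDesignError(LastfitError):
    """Calibration input violates its design assumptions (e.g. unequal slider steps)."""


class ConfigurationError(LastfitError):
    """Invalid configuration (empty search space, bad bounds, ...)."""
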
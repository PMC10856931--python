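"""Exception hierarchy shared across the package."""


class FibredoseError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(FibredoseError):
    """Sensor/source geometry is unphysical (e.g. non-positive lateral distance)."""


class InsideSourceError(InvalidGeometryError):
    """Evaluation point lies inside the source capsule (r <= L/2)."""


class ConfigurationError(FibredoseError):
    """Malformed or inconsistent configuration (tables, thresholds, specs)."""


class DataError(FibredoseError):
    """Invalid measurement data (missing columns, negative counts, bad ordering)."""


class CalibrationError(FibredoseError):
    """No usable reference point for gauging counts against the dose model."""


class FitError(FibredoseError):
    """A least-squares fit failed to converge or the data are degenerate."""


class InsufficientDataError(DataError):
    """Too few points for the requested fit."""
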
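"""Exception hierarchy shared by all metric modules."""


class ColpoQCError(Exception):
    """Base class for all package errors."""


class FormatError(ColpoQCError):
    """Unreadable or malformed image/spectrum file."""


class ParseError(ColpoQCError):
    """Non-numeric or structurally invalid text input."""


class InputError(ColpoQCError):
    """Arguments violate an operation precondition."""


class ResolutionError(InputError):
    """Requested feature is too small for the pixel scale."""


class DetectionError(ColpoQCError):
    """Feature detection found fewer structures than required."""


class ComputationError(ColpoQCError):
    """A metric is undefined for the given (degenerate) input."""


class CalibrationError(ColpoQCError):
    """Physical-scale calibration could not be established."""


class AmbiguousPeakError(ColpoQCError):
    """Spectrum has no well-defined single peak."""


class TruncationError(ColpoQCError):
    """Beam extends past the frame border; FWHM not measurable."""


class UnitsError(ColpoQCError):
    """Absolute (calibrated) units required but relative given."""


class NoSafePowerError(ColpoQCError):
    """Every sampled power exceeds the specular threshold."""


class DataQualityError(ColpoQCError):
    """Measured series violates an expected monotonicity."""


class ConfigError(ColpoQCError):
    """Malformed characterization config file."""
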
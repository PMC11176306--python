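"""Exception and warning hierarchy.

Command-line wrappers map these onto exit codes: configuration/schema
problems exit 2, data/domain problems exit 3.
"""


class PadQuantError(Exception):
    """Base class for all padquant errors."""


# -- configuration / schema problems (CLI exit code 2) -----------------------

class ConfigurationError(PadQuantError):
    """Invalid or incomplete configuration (e.g. missing blank reference)."""


class SchemaError(ConfigurationError):
    """A tabular input is missing a required column."""


class LayoutError(ConfigurationError):
    """A scan layout cannot hold the requested zones."""


# -- data / domain problems (CLI exit code 3) --------------------------------

class DataError(PadQuantError):
    """Base class for problems with the data values themselves."""


class ImageReadError(DataError):
    """A raster file could not be read."""


class ImageFormatError(DataError):
    """A raster decodes to an unsupported colour model (e.g. CMYK)."""


class ParseError(DataError):
    """A cell in a tabular input could not be parsed."""


class ZoneError(DataError):
    """A zone specification selects no pixels or falls outside the raster."""


class DetectionError(DataError):
    """Automatic zone detection found the wrong number of zones."""


class DivisionGuardError(DataError):
    """A ratio method hit a zero denominator channel."""


class DomainError(DataError):
    """A logarithmic method received a non-positive intensity."""


class PairingError(DataError):
    """Zones and blanks passed to the multi-zone distance do not pair up."""


class SingularDesignError(DataError):
    """All calibration concentrations are identical; the slope is undefined."""


class InsufficientDataError(DataError):
    """Too few calibration points to fit a line."""


class UndefinedLODError(DataError):
    """LOD requested for an unusable calibration or a zero slope."""


class UndefinedCIError(DataError):
    """Confidence limit requested with zero residual degrees of freedom."""


# -- warnings ----------------------------------------------------------------

class SaturationWarning(UserWarning):
    """More than 20% of simulated zone means hit the 0/255 clip bounds."""


class ExtrapolationWarning(UserWarning):
    """A requested concentration lies outside the calibrated range."""


class InfiniteRatioWarning(UserWarning):
    """Both uncertainties are zero; the signal ratio is reported as inf."""
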
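"""Exception hierarchy shared across the package."""


class OxsaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OxsaError):
    """A required configuration field is missing or malformed."""


class UnitError(ConfigurationError):
    """A unit string is not recognized for the field it annotates."""


class ParameterValidationError(OxsaError, ValueError):
    """A physiological parameter or model input is out of its valid range."""


class NumericalError(OxsaError):
    """An iterative solver failed to converge or produced invalid values."""


class CFLError(NumericalError):
    """The advection step would move a blood parcel more than one slice."""


class SimulationError(OxsaError):
    """The coupled time-stepping produced a non-finite or invalid state."""


class DataError(OxsaError):
    """An input signal contains invalid samples."""


class FormatError(DataError):
    """A file does not conform to the expected on-disk format."""


class FitError(OxsaError):
    """A parameter fit could not be carried out on the given segment."""


class DegenerateStatisticError(OxsaError):
    """A statistic is undefined for the supplied data (e.g. zero variance)."""
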
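"""Exception hierarchy shared across the package."""


class KaliumError(Exception):
    """Base class for all package-specific errors."""


class FormatError(KaliumError):
    """A file or table does not follow the expected layout."""


class ValidationError(KaliumError):
    """Input data violates a structural or numerical contract."""


class RangeError(KaliumError):
    """A requested wavelength range falls outside the available data."""


class ConfigurationError(KaliumError):
    """A configuration object is internally inconsistent or infeasible."""


class StateError(KaliumError):
    """An operation was applied to an object in the wrong state."""


class DegenerateTargetError(KaliumError):
    """The response variable is constant, so the statistic is undefined."""


class RankError(KaliumError):
    """More latent components requested than the data can support."""


class AlignmentError(KaliumError):
    """Two objects that must share an axis (wavelengths, samples) do not."""
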
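"""Exception and warning types shared across the toolkit."""


class GecilabError(ValueError):
    """Base class for all domain errors raised by gecilab."""


class WindowCoverageError(GecilabError):
    """A spectrum's wavelength grid does not cover a required band window."""


class DegenerateRegressionError(GecilabError):
    """A regression has no information (constant regressor or response)."""


class SignError(GecilabError):
    """A quantity violates its required sign (e.g. titration slope >= 0)."""


class InvalidDenaturedError(GecilabError):
    """The denatured spectrum yields a non-positive band absorbance."""


class SaturatedBufferError(GecilabError):
    """Ca-EGTA fraction of 1 implies unbounded free calcium."""


class UnidentifiableFitError(GecilabError):
    """The data carry no information about the requested parameters."""


class BaselineError(GecilabError):
    """Baseline fluorescence is non-positive or the window is invalid."""


class ChannelError(GecilabError):
    """A reference channel is non-positive where a ratio is required."""


class InsufficientReplicationError(GecilabError):
    """Fewer trials/samples than the statistic requires."""


class NoCycleError(GecilabError):
    """No violet illumination epoch found in a photochromic trace."""


class OrientationError(GecilabError):
    """A calibration curve has the wrong monotonic orientation."""


class CalibrationRangeError(GecilabError):
    """A value falls outside the open range of a calibration curve."""


class MissingReferenceError(GecilabError):
    """No reference cross-section available at the requested wavelength."""


class ConfigError(GecilabError):
    """A synthetic-data configuration is internally inconsistent."""


class FitQualityWarning(UserWarning):
    """The fit converged but the data violate a model assumption."""


class CoverageWarning(UserWarning):
    """Calibration range does not bracket the values being inverted."""
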
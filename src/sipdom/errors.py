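"""Exception hierarchy shared across the package."""


class SipdomError(Exception):
    """Base class for all package-specific errors."""


class InvalidProfileError(SipdomError):
    """A density-gradient profile cannot support a weighted-mean density."""


class PairingError(SipdomError):
    """Labeled and unlabeled profiles cannot be paired (marker/isotope/replicate mismatch)."""


class ImplausibleDensityError(SipdomError):
    """A weighted mean density implies a GC content far outside [0, 1]."""


class DegenerateChemistryError(SipdomError):
    """The maximum-labeling molecular weight does not exceed the light one."""


class CalibrationError(SipdomError):
    """Internal mass calibration failed (too few matched calibrants)."""


class EmptySampleError(SipdomError):
    """A DOM sample has no assigned formulas to normalize."""


class UnclassifiableHabitatError(SipdomError):
    """Sample metadata falls outside every defined habitat category."""


class ConfigError(SipdomError):
    """Invalid simulation or pipeline configuration."""


class ParseError(SipdomError):
    """A delimited input file violates the documented schema."""
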
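"""Exception hierarchy for arterymech.

All package errors derive from :class:`ArteryMechError` so callers can catch
one base class at pipeline boundaries.
"""


class ArteryMechError(Exception):
    """Base class for all arterymech errors."""


class InvalidGeometryError(ArteryMechError):
    """Unloaded ring geometry is non-positive or inverted."""


class InfeasibleDeformationError(ArteryMechError):
    """A deformed configuration cannot accommodate the wall volume.

    Raised when the incompressibility relation would require a negative
    squared inner diameter, i.e. the measured outer diameter is too small
    for the reference wall volume at the given axial stretch.
    """


class InsufficientDataError(ArteryMechError):
    """Not enough records or samples for the requested analysis."""


class ExtrapolationRefusedError(ArteryMechError):
    """A target pressure lies outside the sampled pressure range."""


class IllConditionedFitError(ArteryMechError):
    """Degenerate abscissa spacing makes a local fit meaningless."""


class StiffnessTooLowError(ArteryMechError):
    """The membrane model cannot equilibrate the requested pressure
    within the circumferential-stretch search bracket."""


class ParameterRangeError(ArteryMechError):
    """Constitutive parameters cause numerical overflow (exponent too large)."""


class UndefinedOrientationError(ArteryMechError):
    """An image has no orientation content (zero spectrum after DC removal)."""


class UndefinedRatioError(ArteryMechError):
    """The axial orientation window holds zero mass, so Qc/Qa is undefined."""


class LoopFiberError(ArteryMechError):
    """A traced fiber closes on itself; straightness is undefined."""
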
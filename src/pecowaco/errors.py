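"""Exception hierarchy for the PeCoWaCo analysis pipeline.

Degenerate but expected conditions (constant traces, featureless PIV
windows) are signalled through flags on result objects, not exceptions;
exceptions are reserved for contract violations and unusable inputs.
"""


class PecowacoError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(PecowacoError, ValueError):
    """A synthetic-data specification violates its invariants."""


class GeometryError(PecowacoError, ValueError):
    """Geometry is unusable (contour outside frame, Rc <= Rp, ...)."""


class ResolutionError(PecowacoError, ValueError):
    """A requested structure is not resolvable at the given sampling."""


class SegmentationError(PecowacoError, ValueError):
    """A mask does not contain exactly one clean foreground component."""


class StripError(PecowacoError, ValueError):
    """Contour too short for the requested curvature strip length."""


class BandError(PecowacoError, ValueError):
    """Requested period band is outside the resolvable range."""


class EmptyTracesError(PecowacoError, ValueError):
    """No PIV grid point was valid often enough to build a time series."""


class NotReachedError(PecowacoError, ValueError):
    """Aspiration tongue never reached the pipette radius."""


class NoPeakError(PecowacoError, ValueError):
    """An intensity profile has no peak above baseline."""


class InsufficientScanError(PecowacoError, ValueError):
    """Too few line scans produced a measurable cortical peak."""


class NoWaveError(PecowacoError, ValueError):
    """Kymograph does not pass the oscillation call; no wave to fit."""


class StandingWaveError(PecowacoError, ValueError):
    """Both travel directions carry equal power; no net wave velocity."""
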
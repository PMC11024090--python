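"""Typed exceptions raised by pipeline stages.

Each exception maps onto one failure code in :mod:`reefwarp.pipeline`, so a
batch run can classify why an image aborted without string-matching messages.
"""


class ReefwarpError(Exception):
    """Base class for all pipeline errors."""


class SingularConfigurationError(ReefwarpError):
    """Quad correspondence is degenerate; no invertible homography exists."""


class PointAtInfinityError(ReefwarpError):
    """Homogeneous division by (numerically) zero during point mapping."""


class VerticalDataError(ReefwarpError):
    """All abscissae identical; a slope/intercept line cannot represent the fit."""


class InsufficientViewsError(ReefwarpError):
    """Fewer calibration views than the minimum required."""


class PatternNotFoundError(ReefwarpError):
    """Calibration pattern could not be detected in an image."""


class NoWaterColumnError(ReefwarpError):
    """Too few zero-edge-density pixels to fit a water-column line."""


class NoHorizonError(ReefwarpError):
    """No usable contour separating reef from water."""


class HorizonOffLeftEdgeError(ReefwarpError):
    """Detected horizon does not intersect the left image edge within frame."""


class InsufficientEdgesError(ReefwarpError):
    """Too few edge pixels to compute texture statistics."""


class NoCandidateLinesError(ReefwarpError):
    """Angle/sign filtering left one side of the image without line segments."""


class NoVanishingPointError(ReefwarpError):
    """No left x right intersections survived the horizon/width windows."""


class NoVanishingLineError(ReefwarpError):
    """Every candidate segment was excluded (e.g. above the anisotropy index)."""


class GridLostError(ReefwarpError):
    """Fewer than two grid-line structures recovered from a warped overlay."""


class SearchNonConvergenceError(ReefwarpError):
    """Compression-factor sweep exhausted without the grid reaching 90 degrees."""

    def __init__(self, message: str, final_angle: float | None = None):
        super().__init__(message)
        self.final_angle = final_angle


class ResolutionTooLowError(ReefwarpError):
    """Input below the minimum pixel count for reliable geometry extraction."""


class CalibrationMissingError(ReefwarpError):
    """No camera model available for the requested camera name."""


class FixtureError(ReefwarpError):
    """Synthetic-scene pose places required structure (e.g. horizon) off frame."""
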
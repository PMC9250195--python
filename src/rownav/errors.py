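"""Exception hierarchy for detection-stage failures.

Stage failures (degenerate histogram, no central pair, ...) are recoverable:
``detect_frame`` catches them and reports the failing stage in the result
status instead of raising.
"""


class RowNavError(Exception):
    """Base class for all rownav errors."""


class DegenerateHistogram(RowNavError):
    """The image has fewer than two distinct intensities; Otsu is undefined."""


class NoCentralPair(RowNavError):
    """No crop-row component on one (or both) sides of the image centerline."""


class NoGapFound(RowNavError):
    """No inter-row gap component survived hole suppression inside the ROI."""


class DegenerateFit(RowNavError):
    """Line-fit points do not span two distinct image rows."""


class EmptyRoi(RowNavError):
    """The ROI rectangle is empty after clipping to the image."""


class BehindCamera(RowNavError):
    """A ground point projects from behind the camera (or above the horizon)."""


class ConfigError(RowNavError):
    """Invalid or unknown pipeline/scenario configuration."""
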
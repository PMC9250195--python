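"""Pipeline configuration: every tunable of the detection chain.

Defaults follow the published operating point for seedling cotton:
Canny Gaussian radius 0.3, a 21-row x 7-column structuring element applied
five times, 50-px noise removal, 50-px ROI margin and 1000-px hole
suppression.  Crop presets adjust the Gaussian radius (maize leaves are
long and narrow, so 0.5 reduces excess edge lines).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigError
from .imaging import _EDGE_BACKENDS, StructuringElement

_SE_STYLES = ("rect", "vertical_bar")
_FIT_POINTS = ("all", "row_midpoints")
CROP_PRESETS = {
    "cotton": {"gaussian_radius": 0.3},
    "soybean": {"gaussian_radius": 0.3},
    "corn": {"gaussian_radius": 0.5},
}


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the frame-detection pipeline (all units in pixels
    unless noted)."""

    #: Gaussian radius of the Canny smoothing (0.3 broad-leaved crops,
    #: 0.5 narrow-leaved maize).
    gaussian_radius: float = 0.3
    #: Hysteresis thresholds; None selects the automatic rule
    #: (high = Otsu of the gradient magnitude, low = 0.4 * high).
    canny_low: float | None = None
    canny_high: float | None = None
    #: Edge operator; the non-Canny backends exist for comparison only.
    edge_backend: str = "canny"
    #: Structuring-element footprint (rows, cols) and style.  The default
    #: style activates only the footprint's center column, so expansion
    #: bridges within-row gaps vertically without widening the rows —
    #: a full-rectangle element (style "rect") widens each row by
    #: 3 px/side/iteration and glues the central pair shut.
    se_shape: tuple[int, int] = (21, 7)
    se_style: str = "vertical_bar"
    dilation_iterations: int = 5
    #: Connected domains smaller than this are treated as noise.
    min_component_area: int = 50
    #: Horizontal ROI extension beyond the central pair's outer pixels.
    roi_margin: int = 50
    #: Vertical ROI band as fractions of the image height.
    roi_band: tuple[float, float] = (0.25, 0.75)
    #: Inverted-background domains smaller than this are edge-cut debris.
    max_hole_area: int = 1000
    #: Minimum Otsu foreground/background mean separation (gray levels)
    #: for a frame to count as containing vegetation: soil/mulch-only
    #: frames split at a few gray levels, green rows at 100+.
    min_class_separation: float = 40.0
    #: Map ExG affinely to [0,255] instead of clamping.
    exg_rescale: bool = False
    #: Line-fit feature points: every gap pixel, or one midpoint per row.
    fit_points: str = "all"

    def __post_init__(self):
        if self.gaussian_radius <= 0:
            raise ConfigError("gaussian_radius must be positive")
        if self.edge_backend not in _EDGE_BACKENDS:
            raise ConfigError(f"unknown edge_backend {self.edge_backend!r}")
        if self.se_style not in _SE_STYLES:
            raise ConfigError(f"unknown se_style {self.se_style!r}")
        rows, cols = self.se_shape
        if rows < 1 or cols < 1:
            raise ConfigError("se_shape entries must be >= 1")
        if self.dilation_iterations < 0:
            raise ConfigError("dilation_iterations must be >= 0")
        if self.min_component_area < 0 or self.roi_margin < 0 or self.max_hole_area < 0:
            raise ConfigError("areas and margins must be >= 0")
        if self.min_class_separation < 0:
            raise ConfigError("min_class_separation must be >= 0")
        top, bottom = self.roi_band
        if not (0 <= top < bottom <= 1):
            raise ConfigError("roi_band must satisfy 0 <= top < bottom <= 1")
        if self.fit_points not in _FIT_POINTS:
            raise ConfigError(f"unknown fit_points {self.fit_points!r}")
        if (self.canny_low is None) != (self.canny_high is None):
            if self.canny_low is not None:
                raise ConfigError("canny_low given without canny_high")
        if self.canny_low is not None and self.canny_high is not None:
            if not (0 <= self.canny_low <= self.canny_high):
                raise ConfigError("need 0 <= canny_low <= canny_high")

    def structuring_element(self) -> StructuringElement:
        rows, cols = self.se_shape
        if self.se_style == "rect":
            return StructuringElement.rect(rows, cols)
        return StructuringElement.vertical_bar(rows, cols)

    @classmethod
    def for_crop(cls, crop: str, **overrides) -> "PipelineConfig":
        """Preset for a crop: cotton / soybean (radius 0.3) or corn (0.5)."""
        try:
            preset = dict(CROP_PRESETS[crop])
        except KeyError:
            raise ConfigError(
                f"unknown crop {crop!r}; expected one of {sorted(CROP_PRESETS)}")
        preset.update(overrides)
        return cls.from_mapping(preset)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        """Build a config from a plain dict, rejecting unknown keys."""
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in mapping.items():
            if key not in known:
                raise ConfigError(f"unknown config key {key!r}")
            if key in ("se_shape", "roi_band") and value is not None:
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load a YAML or TOML config file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".toml", ".tml"):
            import tomllib
            data = tomllib.loads(text)
        else:
            import yaml
            data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["se_shape"] = list(self.se_shape)
        d["roi_band"] = list(self.roi_band)
        return d
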
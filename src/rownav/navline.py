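"""Inter-row gap extraction, navigation-line fitting and path kinematics.

The navigation line is the least-squares line through all pixels of the
connected background domain between the two central narrow rows.  Because
that gap runs roughly vertically in the image, the line is parameterized
as ``x = a*y + b`` (x regressed on y): a y-on-x regression would blow up
for near-vertical lines.

The module also carries the two guidance quantities derived from the
line: the lateral error ``m`` between actual and ideal vehicle positions
(plain Euclidean distance) and the predicted yaw rate ``omega_p = v * rho``
for a vehicle of speed ``v`` following a path of curvature ``rho``.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .errors import (DegenerateFit, DegenerateHistogram, EmptyRoi,
                     NoCentralPair, NoGapFound)
from .imaging import (as_rgb, canny_edges, dilate_rows, excess_green,
                      invert, otsu_threshold)
from .rows import (ComponentStats, RoiRect, build_roi, connected_components,
                   remove_small, select_central_pair, separate_rows)


@dataclass(frozen=True)
class NavLine:
    """Navigation line ``x = a*y + b`` in image coordinates.

    ``a`` is the slope dx/dy (dimensionless), ``b`` the x value at the top
    image row, ``support`` the number of pixels used in the fit.
    """

    a: float
    b: float
    support: int

    def __post_init__(self):
        if self.support < 2:
            raise ValueError("a line fit needs support >= 2")
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("line parameters must be finite")

    def x_at(self, y: float) -> float:
        return self.a * y + self.b

    @property
    def heading_deg(self) -> float:
        """Angle between the line and the image vertical, in degrees."""
        return math.degrees(math.atan(self.a))


@dataclass(frozen=True)
class PoseError:
    """Lateral navigation error between actual and ideal vehicle poses."""

    x1: float
    y1: float
    x0: float
    y0: float

    @property
    def m(self) -> float:
        return lateral_error(self.x1, self.y1, self.x0, self.y0)


@dataclass(frozen=True)
class CurvatureState:
    """Path curvature and the predicted yaw (transverse pendulum) rate.

    ``rho`` is the road curvature at the evaluation point, ``rho_dot`` its
    rate of change along arc length scaled by speed, ``omega_p = v * rho``
    the predicted yaw angular velocity; ``s`` is the arc length and
    ``(x, y)`` the center-of-mass coordinates at the evaluation point.
    """

    rho: float
    rho_dot: float
    v: float
    s: float
    x: float
    y: float

    @property
    def omega_p(self) -> float:
        return self.v * self.rho


# ---------------------------------------------------------------------------
# gap extraction and line fitting

def extract_gap(separated, roi: RoiRect, max_hole_area: int = 1000,
                image_width: int | None = None) -> ComponentStats:
    """The inter-row gap domain inside the ROI.

    Within the ROI the separated row mask is inverted so the soil between
    the central rows becomes the target.  Background domains smaller than
    ``max_hole_area`` (default 1000 px) are edge-cut debris and are
    suppressed; of the survivors, the domain whose centroid is nearest the
    image centerline is the gap.  Its pixel coordinates are returned in
    full-image coordinates.

    Raises
    ------
    NoGapFound
        If no background domain survives suppression.
    """
    separated = np.asarray(separated)
    if max_hole_area < 0:
        raise ValueError("max_hole_area must be >= 0")
    w = image_width if image_width is not None else separated.shape[1]
    sub = separated[roi.slices]
    comps = connected_components(invert(sub))
    comps = [c for c in comps if c.area >= max_hole_area]
    if not comps:
        raise NoGapFound("no background domain survived hole suppression")
    center = (w - 1) / 2.0
    best = min(comps, key=lambda c: (abs(c.centroid[0] + roi.x_min - center),
                                     -c.area, c.label))
    pixels = best.pixels + np.array([roi.x_min, roi.y_min])
    return ComponentStats(
        label=best.label,
        area=best.area,
        centroid=(best.centroid[0] + roi.x_min, best.centroid[1] + roi.y_min),
        bbox=(best.bbox[0] + roi.x_min, best.bbox[1] + roi.y_min,
              best.bbox[2] + roi.x_min, best.bbox[3] + roi.y_min),
        pixels=pixels,
    )


def fit_line(points) -> NavLine:
    """Least-squares navigation line through feature points.

    ``points`` is an ``(N, 2)`` array with columns (x, y).  The fit
    minimizes the squared horizontal residuals ``sum (x_i - a*y_i - b)^2``.

    Raises
    ------
    DegenerateFit
        If fewer than two points are given or all share one image row.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array of (x, y)")
    if len(pts) < 2 or np.unique(pts[:, 1]).size < 2:
        raise DegenerateFit("need >= 2 points spanning >= 2 distinct y values")
    a, b = np.polyfit(pts[:, 1], pts[:, 0], 1)
    return NavLine(a=float(a), b=float(b), support=len(pts))


def row_midpoints(points) -> np.ndarray:
    """One (mean-x, y) feature point per distinct image row of the gap."""
    pts = np.asarray(points, dtype=np.float64)
    ys, inverse = np.unique(pts[:, 1], return_inverse=True)
    sums = np.bincount(inverse, weights=pts[:, 0])
    counts = np.bincount(inverse)
    return np.column_stack([sums / counts, ys])


def lateral_error(x1: float, y1: float, x0: float, y0: float) -> float:
    """Lateral navigation error: Euclidean distance between actual
    position ``(x1, y1)`` and ideal position ``(x0, y0)``."""
    for v in (x1, y1, x0, y0):
        if not math.isfinite(v):
            raise ValueError("coordinates must be finite")
    return math.hypot(x1 - x0, y1 - y0)


# ---------------------------------------------------------------------------
# path kinematics

def path_kinematics(traj, v: float, *, x_eval: float = 0.0,
                    step: float = 1e-3) -> CurvatureState:
    """Curvature state of a trajectory and the predicted yaw rate.

    ``traj`` is either a callable ``y(x)`` (differentiated numerically by
    central differences with the given ``step``) or a sampled trajectory:
    an ``(N, 2)`` array of (x, y) with N >= 5, differentiated with
    ``np.gradient`` and evaluated at the sample nearest ``x_eval``.

    The curvature is ``rho = y'' / (1 + y'^2)^(3/2)`` at ``x = x_eval``,
    its rate of change along arc length is ``rho_dot = v * (drho/dx) /
    (ds/dx)`` with ``ds/dx = sqrt(1 + y'^2)``, and the predicted yaw rate
    is ``omega_p = v * rho`` (exact by construction).
    """
    if v < 0:
        raise ValueError("speed must be >= 0")

    if callable(traj):
        h = step

        def d1(x):
            return (traj(x + h) - traj(x - h)) / (2 * h)

        def d2(x):
            return (traj(x + h) - 2 * traj(x) + traj(x - h)) / (h * h)

        def rho_at(x):
            yp = d1(x)
            return d2(x) / (1 + yp * yp) ** 1.5

        yp0 = d1(x_eval)
        rho = rho_at(x_eval)
        drho_dx = (rho_at(x_eval + h) - rho_at(x_eval - h)) / (2 * h)
        ds_dx = math.sqrt(1 + yp0 * yp0)
        return CurvatureState(rho=float(rho),
                              rho_dot=float(v * drho_dx / ds_dx),
                              v=float(v), s=0.0,
                              x=float(x_eval), y=float(traj(x_eval)))

    pts = np.asarray(traj, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise ValueError("sampled trajectory must be an (N, 2) array, N >= 5")
    x, y = pts[:, 0], pts[:, 1]
    yp = np.gradient(y, x)
    ypp = np.gradient(yp, x)
    rho_arr = ypp / (1 + yp ** 2) ** 1.5
    drho_dx = np.gradient(rho_arr, x)
    ds_dx = np.sqrt(1 + yp ** 2)
    seg = np.hypot(np.diff(x), np.diff(y))
    s_arr = np.concatenate([[0.0], np.cumsum(seg)])
    i = int(np.argmin(np.abs(x - x_eval)))
    return CurvatureState(rho=float(rho_arr[i]),
                          rho_dot=float(v * drho_dx[i] / ds_dx[i]),
                          v=float(v), s=float(s_arr[i]),
                          x=float(x[i]), y=float(y[i]))


# ---------------------------------------------------------------------------
# frame orchestration

#: Detection statuses; anything but "ok" names the failed stage's outcome.
STATUS_OK = "ok"
_STAGE_FAILURES = {
    DegenerateHistogram: ("otsu", "degenerate_histogram"),
    NoCentralPair: ("select_central_pair", "no_central_pair"),
    EmptyRoi: ("build_roi", "empty_roi"),
    NoGapFound: ("extract_gap", "no_gap"),
    DegenerateFit: ("fit_line", "degenerate_fit"),
}


@dataclass
class DetectionResult:
    """Per-frame outcome: the navigation line plus stage artifacts.

    ``status`` is ``"ok"`` on success, otherwise a tag naming the failure
    (``degenerate_histogram``, ``no_central_pair``, ``empty_roi``,
    ``no_gap``, ``degenerate_fit``); ``failed_stage`` names the pipeline
    stage that raised.  ``stages`` holds intermediate rasters when
    requested.
    """

    status: str
    line: NavLine | None = None
    failed_stage: str | None = None
    threshold: int | None = None
    roi: RoiRect | None = None
    timings_ms: dict = field(default_factory=dict)
    stages: dict | None = None

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK

    def to_dict(self) -> dict:
        d = {
            "status": self.status,
            "failed_stage": self.failed_stage,
            "threshold": self.threshold,
            "line": None,
            "roi": None,
            "timings_ms": {k: round(v, 3) for k, v in self.timings_ms.items()},
        }
        if self.line is not None:
            d["line"] = {"a": self.line.a, "b": self.line.b,
                         "support": self.line.support}
        if self.roi is not None:
            d["roi"] = [self.roi.x_min, self.roi.y_min,
                        self.roi.x_max, self.roi.y_max]
        return d


def detect_frame(image, config: PipelineConfig | None = None,
                 *, keep_stages: bool = False) -> DetectionResult:
    """Run the full detection chain on one frame.

    Stages: ExG grayscale -> {Otsu binarization, Canny edges} -> iterated
    dilation -> edge-cut separation -> noise removal -> central-pair
    selection -> ROI -> gap extraction -> least-squares line fit.  A valid
    image never raises: stage failures are encoded in the result status.
    """
    cfg = config if config is not None else PipelineConfig()
    img = as_rgb(image)
    h, w = img.shape[:2]
    timings: dict[str, float] = {}
    stages: dict = {}

    def timed(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        out = fn(*args, **kwargs)
        timings[name] = (time.perf_counter() - t0) * 1e3
        return out

    result = DetectionResult(status=STATUS_OK, timings_ms=timings,
                             stages=stages if keep_stages else None)
    try:
        gray = timed("excess_green", excess_green, img, rescale=cfg.exg_rescale)
        if keep_stages:
            stages["gray"] = gray
        threshold, mask = timed("otsu_threshold", otsu_threshold, gray)
        result.threshold = threshold
        # vegetation-presence guard: an all-soil/mulch frame still splits
        # under Otsu, but only by a few gray levels; green rows sit 100+
        # levels above the background on the ExG map
        fg = mask > 0
        if float(gray[fg].mean()) - float(gray[~fg].mean()) \
                < cfg.min_class_separation:
            result.status = "low_contrast"
            result.failed_stage = "otsu"
            return result
        edges = timed("canny_edges", canny_edges, gray, cfg.gaussian_radius,
                      cfg.canny_low, cfg.canny_high, backend=cfg.edge_backend)
        dilated = timed("dilate_rows", dilate_rows, mask,
                        cfg.structuring_element(), cfg.dilation_iterations)
        separated = timed("separate_rows", separate_rows, dilated, edges)
        if keep_stages:
            stages.update(mask=mask, edges=edges, dilated=dilated,
                          separated=separated)
        comps = timed("connected_components", connected_components, separated)
        comps = remove_small(comps, cfg.min_component_area)
        left, right = timed("select_central_pair", select_central_pair, comps, w)
        roi = timed("build_roi", build_roi, left, right, cfg.roi_margin,
                    cfg.roi_band, (h, w))
        result.roi = roi
        gap = timed("extract_gap", extract_gap, separated, roi,
                    cfg.max_hole_area, w)
        if keep_stages:
            stages["gap"] = gap
        points = gap.pixels
        if cfg.fit_points == "row_midpoints":
            points = row_midpoints(points)
        result.line = timed("fit_line", fit_line, points)
    except tuple(_STAGE_FAILURES) as exc:
        stage, status = _STAGE_FAILURES[type(exc)]
        result.status = status
        result.failed_stage = stage
    return result
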
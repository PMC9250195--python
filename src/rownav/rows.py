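"""Connected-domain analysis and central crop-row selection.

After thresholding, dilation and edge cutting, the frame is a set of
connected domains.  This module labels them (4-connectivity), drops noise
specks, picks the two domains closest to the image centerline — one on
each side, the central narrow-row pair — and builds the region of interest
in which the inter-row gap is extracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .errors import EmptyRoi, NoCentralPair
from .imaging import CONNECTIVITY_4, as_mask, edge_cut


@dataclass(frozen=True, eq=False)
class ComponentStats:
    """A connected foreground domain.

    ``centroid`` is ``(cx, cy)`` in pixel coordinates, ``bbox`` is the
    inclusive ``(x_min, y_min, x_max, y_max)`` rectangle, ``pixels`` an
    ``(N, 2)`` integer array with columns (x, y).
    """

    label: int
    area: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    pixels: np.ndarray

    def __post_init__(self):
        if self.area < 1 or self.area != len(self.pixels):
            raise ValueError("area must equal the number of pixels and be >= 1")


@dataclass(frozen=True)
class RoiRect:
    """Inclusive region-of-interest rectangle in image coordinates."""

    x_min: int
    x_max: int
    y_min: int
    y_max: int

    def __post_init__(self):
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValueError("ROI must be non-empty")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.y_min, self.y_max + 1),
                slice(self.x_min, self.x_max + 1))

    @property
    def width(self) -> int:
        return self.x_max - self.x_min + 1

    @property
    def height(self) -> int:
        return self.y_max - self.y_min + 1


def connected_components(mask) -> list[ComponentStats]:
    """4-connected labeling of the foreground, in raster order of first pixel."""
    m = as_mask(mask) > 0
    lab, n = ndi.label(m, structure=CONNECTIVITY_4)
    if n == 0:
        return []
    ys, xs = np.nonzero(lab)
    labs = lab[ys, xs]
    order = np.argsort(labs, kind="stable")
    xs, ys, labs = xs[order], ys[order], labs[order]
    areas = np.bincount(labs, minlength=n + 1)[1:]
    sum_x = np.bincount(labs, weights=xs, minlength=n + 1)[1:]
    sum_y = np.bincount(labs, weights=ys, minlength=n + 1)[1:]
    stops = np.cumsum(areas)
    starts = stops - areas
    out = []
    for i in range(n):
        px = xs[starts[i]:stops[i]]
        py = ys[starts[i]:stops[i]]
        out.append(ComponentStats(
            label=i + 1,
            area=int(areas[i]),
            centroid=(sum_x[i] / areas[i], sum_y[i] / areas[i]),
            bbox=(int(px.min()), int(py.min()), int(px.max()), int(py.max())),
            pixels=np.column_stack([px, py]),
        ))
    return out


def remove_small(components: list[ComponentStats],
                 min_area: int = 50) -> list[ComponentStats]:
    """Drop noise domains: keep only components with ``area >= min_area``.

    The default of 50 px removes specks while a 50-px domain still survives
    (only strictly smaller areas are treated as noise).
    """
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    return [c for c in components if c.area >= min_area]


def select_central_pair(components: list[ComponentStats],
                        image_width: int) -> tuple[ComponentStats, ComponentStats]:
    """The two crop-row domains closest to the image centerline, one per side.

    The centerline is the column ``x = (W - 1) / 2``.  On each side the
    component minimizing the centroid distance to the centerline wins; ties
    go to the larger area, then the smaller label.  The navigation line must
    run between a left and a right row, so a frame lacking a candidate on
    either side is undetectable.
    """
    center = (image_width - 1) / 2.0

    def best(cands):
        return min(cands, key=lambda c: (abs(c.centroid[0] - center),
                                         -c.area, c.label))

    left = [c for c in components if c.centroid[0] < center]
    right = [c for c in components if c.centroid[0] > center]
    if not left or not right:
        raise NoCentralPair(
            f"need one component on each side of x={center}; "
            f"got {len(left)} left, {len(right)} right")
    return best(left), best(right)


def build_roi(left: ComponentStats, right: ComponentStats,
              margin: int = 50, band: tuple[float, float] = (0.25, 0.75),
              image_shape: tuple[int, int] = (480, 640)) -> RoiRect:
    """ROI around the central pair.

    Horizontally the ROI runs from the leftmost pixel of the left domain
    extended ``margin`` px leftward to the rightmost pixel of the right
    domain extended ``margin`` px rightward.  Vertically it is the
    fractional band ``(top_frac, bottom_frac)`` of the image height —
    default the middle half, which avoids both the row breakage near the
    bottom and the row adhesion near the top.  Everything is clipped to the
    image.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    top, bottom = band
    if not (0 <= top < bottom <= 1):
        raise ValueError("band must satisfy 0 <= top < bottom <= 1")
    h, w = image_shape
    x_min = max(0, left.bbox[0] - margin)
    x_max = min(w - 1, right.bbox[2] + margin)
    y_min = max(0, int(top * h))
    y_max = min(h - 1, int(bottom * h))
    if x_min > x_max or y_min > y_max:
        raise EmptyRoi("ROI is empty after clipping")
    return RoiRect(x_min, x_max, y_min, y_max)


def separate_rows(dilated, edges) -> np.ndarray:
    """Split adhered rows: cut the dilated row mask along the edge map.

    Dilation strengthens far-field adhesion between the two narrow rows;
    the Canny leaf contours run along the true row boundaries, so zeroing
    the dilated mask under them restores separate row domains.
    """
    return edge_cut(dilated, edges)
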
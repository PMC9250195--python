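"""Pixel-level operators of the row-detection pipeline.

The pipeline works on plain numpy rasters with a fixed set of conventions:

* colour frames are ``(H, W, 3)`` uint8 arrays in R, G, B channel order;
* grayscale maps are ``(H, W)`` uint8;
* binary masks and edge maps are ``(H, W)`` uint8 taking only the values
  0 (background) and 255 (target);
* the origin is the top-left pixel, ``x`` is the column index growing
  rightward, ``y`` the row index growing downward.

The operators here are the vegetation index (ExG), global Otsu
thresholding, Canny edge extraction, the vertically elongated dilation
used to bridge within-row seedling gaps, and the edge-cut that splits
adhered rows along detected leaf contours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage import feature, filters

from .errors import DegenerateHistogram

FOREGROUND = 255

#: 4-connectivity structure used for every connected-domain operation, so
#: that a one-pixel (8-connected) edge cut genuinely separates regions.
CONNECTIVITY_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


# ---------------------------------------------------------------------------
# validation helpers

def as_rgb(image) -> np.ndarray:
    """Validate and return an RGB frame as a ``(H, W, 3)`` uint8 array."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must have at least one row and one column")
    if arr.dtype != np.uint8:
        if np.any(arr < 0) or np.any(arr > 255):
            raise ValueError("intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def as_gray(image) -> np.ndarray:
    """Validate and return a grayscale map as a ``(H, W)`` uint8 array."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected (H, W) grayscale image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if np.any(arr < 0) or np.any(arr > 255):
            raise ValueError("intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def as_mask(mask) -> np.ndarray:
    """Validate and return a binary mask (values 0/255 only)."""
    arr = as_gray(mask)
    if not np.isin(arr, (0, FOREGROUND)).all():
        raise ValueError("binary mask may only contain the values 0 and 255")
    return arr


# ---------------------------------------------------------------------------
# vegetation index

def excess_green(image, *, rescale: bool = False) -> np.ndarray:
    """Excess Green Index grayscale map, ``2G - R - B`` per pixel.

    With ``rescale=False`` (default) the raw index (range -510..510) is
    clamped to [0, 255]: soil and mulch, where red and blue dominate, map
    to exactly 0, leaving only green vegetation highlighted.  With
    ``rescale=True`` the full range is mapped affinely onto [0, 255]
    (gray = 127/128), which preserves sub-zero contrast at the cost of
    background suppression.
    """
    img = as_rgb(image).astype(np.int32)
    exg = 2 * img[..., 1] - img[..., 0] - img[..., 2]
    if rescale:
        exg = np.rint((exg + 510) * (255.0 / 1020.0)).astype(np.int32)
    return np.clip(exg, 0, 255).astype(np.uint8)


def column_profile(gray) -> np.ndarray:
    """Column-wise intensity accumulation (length-W vector).

    Diagnostic only: peaks of the profile sit on the crop rows and show why
    ExG separates rows better than the raw G channel.
    """
    return as_gray(gray).sum(axis=0, dtype=np.int64)


# ---------------------------------------------------------------------------
# Otsu thresholding

def otsu_threshold(gray) -> tuple[int, np.ndarray]:
    """Global Otsu threshold and the resulting binary mask.

    The threshold ``t`` maximizes the between-class variance of the 256-bin
    intensity histogram (class 0: intensity <= t, class 1: intensity > t);
    ties go to the smallest t.  The mask is 255 exactly where the intensity
    strictly exceeds ``t``.

    Raises
    ------
    DegenerateHistogram
        If the image holds fewer than two distinct intensities.
    """
    g = as_gray(gray)
    hist = np.bincount(g.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogram("image has a single intensity value")
    w0 = np.cumsum(hist)
    csum = np.cumsum(hist * np.arange(256))
    w1 = w0[-1] - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(w0 > 0, csum / w0, 0.0)
        mu1 = np.where(w1 > 0, (csum[-1] - csum) / w1, 0.0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    between[(w0 == 0) | (w1 == 0)] = -1.0
    t = int(np.argmax(between))
    mask = np.where(g > t, FOREGROUND, 0).astype(np.uint8)
    return t, mask


def _otsu_scalar(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold of an arbitrary float sample (used for gradient maps)."""
    values = np.asarray(values, dtype=np.float64).ravel()
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return hi
    hist, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = hist.astype(np.float64)
    w0 = np.cumsum(hist)
    csum = np.cumsum(hist * centers)
    w1 = w0[-1] - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(w0 > 0, csum / w0, 0.0)
        mu1 = np.where(w1 > 0, (csum[-1] - csum) / w1, 0.0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    between[(w0 == 0) | (w1 == 0)] = -1.0
    return float(centers[np.argmax(between)])


# ---------------------------------------------------------------------------
# edge detection

_EDGE_BACKENDS = ("canny", "sobel", "prewitt", "roberts")


def canny_edges(gray, gaussian_radius: float = 0.3,
                low: float | None = None, high: float | None = None,
                *, backend: str = "canny") -> np.ndarray:
    """Edge map of the ExG grayscale image.

    The default backend is the Canny operator at a small Gaussian radius
    (0.3), which keeps the fine leaf contours needed to cut adhered rows
    apart; a radius of 0.5 suits long narrow leaves (maize) where 0.3
    produces excessive edge clutter.  Hysteresis thresholds default to an
    automatic rule: ``high`` is the Otsu threshold of the gradient
    magnitude and ``low = 0.4 * high``.

    ``sobel``/``prewitt``/``roberts`` backends are provided only for
    operator comparison; they threshold the gradient magnitude at its Otsu
    level after the same Gaussian smoothing.

    Returns a 0/255 uint8 edge map.
    """
    if gaussian_radius <= 0:
        raise ValueError("gaussian_radius must be positive")
    if backend not in _EDGE_BACKENDS:
        raise ValueError(f"unknown edge backend {backend!r}; expected one of {_EDGE_BACKENDS}")
    g = as_gray(gray).astype(np.float64) / 255.0

    if backend == "canny":
        if high is None:
            smoothed = ndi.gaussian_filter(g, gaussian_radius, mode="reflect")
            mag = np.hypot(ndi.sobel(smoothed, axis=0), ndi.sobel(smoothed, axis=1))
            if mag.max() <= 0:
                return np.zeros(g.shape, dtype=np.uint8)
            high = _otsu_scalar(mag)
        if low is None:
            low = 0.4 * high
        if not (0 <= low <= high):
            raise ValueError("thresholds must satisfy 0 <= low <= high")
        edges = feature.canny(g, sigma=gaussian_radius,
                              low_threshold=low, high_threshold=high)
    else:
        op = {"sobel": filters.sobel, "prewitt": filters.prewitt,
              "roberts": filters.roberts}[backend]
        mag = op(ndi.gaussian_filter(g, gaussian_radius, mode="reflect"))
        if mag.max() <= 0:
            return np.zeros(g.shape, dtype=np.uint8)
        thr = high if high is not None else _otsu_scalar(mag)
        edges = mag > thr
    return edges.astype(np.uint8) * FOREGROUND


def edge_coordinates(edges) -> np.ndarray:
    """Coordinate array T of edge pixels, shape ``(N, 2)`` with columns (x, y)."""
    e = as_mask(edges)
    ys, xs = np.nonzero(e)
    return np.column_stack([xs, ys])


# ---------------------------------------------------------------------------
# morphology

@dataclass(frozen=True, eq=False)
class StructuringElement:
    """Morphological structuring element: boolean footprint plus origin anchor.

    ``footprint`` has shape (rows, cols); ``origin`` is the (row, col)
    anchor inside it.
    """

    footprint: np.ndarray
    origin: tuple[int, int]

    def __post_init__(self):
        fp = np.asarray(self.footprint, dtype=bool)
        object.__setattr__(self, "footprint", fp)
        if fp.ndim != 2 or not fp.any():
            raise ValueError("footprint must be 2-D with at least one true cell")
        r, c = self.origin
        if not (0 <= r < fp.shape[0] and 0 <= c < fp.shape[1]):
            raise ValueError("origin must lie inside the footprint")

    @classmethod
    def rect(cls, rows: int = 21, cols: int = 7) -> "StructuringElement":
        """Full rectangle, anchored at the center.

        The default 21-row x 7-column element is vertically elongated so the
        dilation bridges within-row seedling gaps far faster than it widens
        the rows.
        """
        fp = np.ones((rows, cols), dtype=bool)
        return cls(fp, ((rows - 1) // 2, (cols - 1) // 2))

    @classmethod
    def vertical_bar(cls, rows: int = 21, cols: int = 7) -> "StructuringElement":
        """A single active center column inside a rows x cols footprint.

        Grows masks strictly vertically (the width of the white area on the
        horizontal axis is unaffected).
        """
        fp = np.zeros((rows, cols), dtype=bool)
        fp[:, (cols - 1) // 2] = True
        return cls(fp, ((rows - 1) // 2, (cols - 1) // 2))


def dilate_rows(mask, se: StructuringElement | None = None,
                iterations: int = 5) -> np.ndarray:
    """Iterated binary dilation used to bridge broken rows.

    Defaults: the 21x7 vertical-bar element applied five times, enough to
    close typical within-row seedling gaps while the rows stay apart (the
    expansion grows masks vertically only).
    """
    m = as_mask(mask)
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return m.copy()
    se = se if se is not None else StructuringElement.vertical_bar()
    center = ((se.footprint.shape[0] - 1) // 2, (se.footprint.shape[1] - 1) // 2)
    # scipy's origin offsets the element so that our anchor acts as the
    # placement point: a point at p dilates to {p + s - anchor, s in SE}
    origin = (se.origin[0] - center[0], se.origin[1] - center[1])
    out = ndi.binary_dilation(m > 0, structure=se.footprint,
                              iterations=iterations, origin=origin)
    return out.astype(np.uint8) * FOREGROUND


def invert(mask) -> np.ndarray:
    """Swap foreground and background (0 <-> 255)."""
    return (FOREGROUND - as_mask(mask)).astype(np.uint8)


def edge_cut(rows, edges) -> np.ndarray:
    """Cut the (dilated) row mask along the edge map: ``rows AND NOT edges``.

    Every row pixel under an edge pixel is zeroed, so leaf contours detected
    by Canny carve adhered rows apart; the output never gains foreground.
    """
    r = as_mask(rows)
    e = as_mask(edges)
    if r.shape != e.shape:
        raise ValueError(f"shape mismatch: rows {r.shape} vs edges {e.shape}")
    out = r.copy()
    out[e > 0] = 0
    return out
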
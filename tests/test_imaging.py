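"""Pixel-operator tests: vegetation index, Otsu, Canny, morphology."""

import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rownav import (DegenerateHistogram, StructuringElement, canny_edges,
                    column_profile, dilate_rows, edge_coordinates, edge_cut,
                    excess_green, invert, otsu_threshold)

from conftest import random_mask

# ---------------------------------------------------------------------------
# ExG


@pytest.mark.parametrize("rgb,expected", [
    ((100, 100, 100), 0),      # gray: 2G - R - B = 0
    ((0, 255, 0), 255),        # pure green, clamped from 510
    ((60, 120, 40), 140),      # 240 - 60 - 40
    ((200, 10, 200), 0),       # negative index clamps to zero
])
def test_excess_green_single_pixel(rgb, expected):
    img = np.full((3, 4, 3), rgb, dtype=np.uint8)
    assert excess_green(img)[1, 2] == expected


def test_excess_green_rescale_maps_midpoint_to_gray():
    img = np.full((2, 2, 3), 100, dtype=np.uint8)  # raw index 0
    assert excess_green(img, rescale=True)[0, 0] in (127, 128)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(hnp.arrays(np.uint8, (5, 5, 3), elements=st.integers(40, 200)),
       st.integers(-30, 30))
def test_excess_green_invariant_to_common_offset(img, c):
    """Adding c to all channels leaves 2G-R-B unchanged away from clamps."""
    shifted = np.clip(img.astype(int) + c, 0, 255).astype(np.uint8)
    base = excess_green(img)
    # compare only where neither version clamps (raw index within (0, 255))
    raw = 2 * img[..., 1].astype(int) - img[..., 0] - img[..., 2]
    interior = (raw > 0) & (raw < 255) & (shifted.min(axis=-1) > 0) \
        & (shifted.max(axis=-1) < 255)
    assert np.array_equal(excess_green(shifted)[interior], base[interior])


def test_column_profile_sums_columns():
    gray = np.array([[1, 2], [3, 4]], dtype=np.uint8)
    assert column_profile(gray).tolist() == [4, 6]
    assert column_profile(np.zeros((4, 3), np.uint8)).tolist() == [0, 0, 0]
    uniform = np.full((7, 5), 9, np.uint8)
    assert column_profile(uniform).tolist() == [63] * 5


# ---------------------------------------------------------------------------
# Otsu


def otsu_exhaustive(gray):
    """Independent oracle: scan all 256 candidate thresholds directly."""
    g = np.asarray(gray).ravel().astype(np.float64)
    best_t, best_v = 0, -1.0
    for t in range(256):
        lo, hi = g[g <= t], g[g > t]
        if lo.size == 0 or hi.size == 0:
            continue
        v = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def test_otsu_separates_bimodal_image():
    gray = np.concatenate([np.full(32, 10), np.full(32, 200)])
    gray = np.tile(gray, (8, 1)).astype(np.uint8)
    t, mask = otsu_threshold(gray)
    assert 10 <= t < 200
    assert np.array_equal(mask > 0, gray == 200)


def test_otsu_matches_exhaustive_scan_and_skimage():
    from skimage.filters import threshold_otsu
    rng = np.random.default_rng(42)
    for _ in range(10):
        gray = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        t, mask = otsu_threshold(gray)
        assert t == otsu_exhaustive(gray)
        assert abs(t - threshold_otsu(gray)) <= 1
        assert np.array_equal(mask > 0, gray > t)


def test_otsu_rejects_constant_image():
    with pytest.raises(DegenerateHistogram):
        otsu_threshold(np.full((8, 8), 7, np.uint8))


# ---------------------------------------------------------------------------
# Canny


def test_canny_uniform_image_has_no_edges():
    assert canny_edges(np.full((16, 16), 80, np.uint8)).sum() == 0


def test_canny_ideal_step_gives_single_column():
    gray = np.zeros((32, 32), np.uint8)
    gray[:, 16:] = 255
    edges = canny_edges(gray, gaussian_radius=0.3)
    ys, xs = np.nonzero(edges)
    assert set(np.unique(xs)) <= {15, 16}     # confined to the step columns
    # every interior row detects the edge (the exact NMS tie on a
    # perfectly symmetric step may keep both adjacent columns, and the
    # image border rows are masked out)
    assert set(range(1, 31)) <= set(np.unique(ys))


def reference_canny(gray, sigma, low, high):
    """Independent compact Canny: quantized-direction NMS + hysteresis."""
    g = ndi.gaussian_filter(gray.astype(float) / 255.0, sigma)
    gy, gx = ndi.sobel(g, axis=0), ndi.sobel(g, axis=1)
    mag = np.hypot(gy, gx)
    ang = np.rad2deg(np.arctan2(gy, gx)) % 180
    h, w = mag.shape
    nms = np.zeros_like(mag)
    for y in range(1, h - 1):
        for x in range(1, w - 1):
            a = ang[y, x]
            if a < 22.5 or a >= 157.5:
                n1, n2 = mag[y, x - 1], mag[y, x + 1]
            elif a < 67.5:
                n1, n2 = mag[y - 1, x + 1], mag[y + 1, x - 1]
            elif a < 112.5:
                n1, n2 = mag[y - 1, x], mag[y + 1, x]
            else:
                n1, n2 = mag[y - 1, x - 1], mag[y + 1, x + 1]
            if mag[y, x] >= n1 and mag[y, x] >= n2:
                nms[y, x] = mag[y, x]
    strong = nms > high
    weak = nms > low
    lab, n = ndi.label(weak, structure=np.ones((3, 3)))
    keep = np.isin(lab, np.unique(lab[strong & (lab > 0)]))
    return keep & weak


def test_canny_agrees_with_reference_implementation():
    """Same smooth two-region image, same thresholds: the two edge sets
    overlap strongly (NMS tie-break details differ between codings)."""
    rng = np.random.default_rng(5)
    gray = np.zeros((48, 48))
    gray[:, 24:] = 180
    gray = ndi.gaussian_filter(gray, 2.0) + rng.normal(0, 2.0, (48, 48))
    gray = np.clip(gray, 0, 255).astype(np.uint8)
    low, high = 0.08, 0.2
    mine = canny_edges(gray, 1.0, low, high) > 0
    ref = reference_canny(gray, 1.0, low, high)
    inter = (mine & ref).sum()
    union = (mine | ref).sum()
    assert union > 0 and inter / union >= 0.5


def test_canny_parameter_validation():
    gray = np.zeros((8, 8), np.uint8)
    with pytest.raises(ValueError):
        canny_edges(gray, gaussian_radius=0.0)
    with pytest.raises(ValueError):
        canny_edges(gray, 0.3, low=0.5, high=0.2)
    with pytest.raises(ValueError):
        canny_edges(gray, 0.3, backend="laplace")


@pytest.mark.parametrize("backend", ["sobel", "prewitt", "roberts"])
def test_alternative_edge_backends_find_the_step(backend):
    gray = np.zeros((32, 32), np.uint8)
    gray[:, 16:] = 255
    edges = canny_edges(gray, 0.5, backend=backend)
    ys, xs = np.nonzero(edges)
    assert len(ys) > 0
    assert np.all(np.abs(xs - 15.5) <= 2.5)


def test_edge_coordinates_lists_exactly_the_edge_pixels():
    edges = np.zeros((5, 5), np.uint8)
    edges[1, 2] = edges[3, 4] = 255
    t = edge_coordinates(edges)
    assert sorted(map(tuple, t)) == [(2, 1), (4, 3)]


# ---------------------------------------------------------------------------
# morphology


def test_structuring_element_validation():
    with pytest.raises(ValueError):
        StructuringElement(np.zeros((3, 3), bool), (1, 1))
    with pytest.raises(ValueError):
        StructuringElement(np.ones((3, 3), bool), (3, 0))


def test_dilate_point_with_full_rect_gives_centered_block():
    mask = np.zeros((41, 41), np.uint8)
    mask[20, 20] = 255
    out = dilate_rows(mask, StructuringElement.rect(21, 7), 1)
    ys, xs = np.nonzero(out)
    assert (ys.min(), ys.max(), xs.min(), xs.max()) == (10, 30, 17, 23)
    assert out.sum() // 255 == 21 * 7


def test_dilate_vertical_bar_preserves_width():
    mask = np.zeros((64, 64), np.uint8)
    mask[30:33, 30:33] = 255
    out = dilate_rows(mask, StructuringElement.vertical_bar(21, 7), 5)
    ys, xs = np.nonzero(out)
    assert xs.min() == 30 and xs.max() == 32   # width untouched
    # 10 px of growth per side per iteration, clipped at the borders
    assert ys.min() == 0 and ys.max() == 63


def test_dilate_empty_and_zero_iterations():
    empty = np.zeros((10, 10), np.uint8)
    assert dilate_rows(empty, iterations=5).sum() == 0
    mask = random_mask(np.random.default_rng(0), (10, 10))
    assert np.array_equal(dilate_rows(mask, iterations=0), mask)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_dilation_laws(seed):
    """Extensivity, monotonicity, and iteration composition."""
    rng = np.random.default_rng(seed)
    m1 = random_mask(rng, (48, 48), 0.08)
    extra = random_mask(rng, (48, 48), 0.05)
    m2 = np.maximum(m1, extra)
    se = StructuringElement.rect(7, 3)
    d1, d2 = dilate_rows(m1, se, 2), dilate_rows(m2, se, 2)
    assert np.all(d1 >= m1)                    # extensive
    assert np.all(d2 >= d1)                    # monotone
    se2 = StructuringElement.rect(13, 5)       # rect composed with itself
    assert np.array_equal(dilate_rows(m1, se, 2), dilate_rows(m1, se2, 1))


def test_invert_involution_and_values():
    rng = np.random.default_rng(3)
    mask = random_mask(rng)
    assert np.array_equal(invert(invert(mask)), mask)
    assert invert(np.full((4, 4), 255, np.uint8)).sum() == 0
    checker = (np.indices((6, 6)).sum(axis=0) % 2 * 255).astype(np.uint8)
    assert np.array_equal(invert(checker), 255 - checker)


def test_edge_cut_removes_edges_only():
    rng = np.random.default_rng(11)
    rows = random_mask(rng, density=0.5)
    edges = random_mask(rng, density=0.1)
    out = edge_cut(rows, edges)
    assert np.all(out <= rows)                       # never adds foreground
    assert not np.any((out > 0) & (edges > 0))       # edges are zeroed
    assert np.array_equal(edge_cut(rows, np.zeros_like(rows)), rows)
    assert edge_cut(np.zeros_like(rows), edges).sum() == 0


def test_edge_cut_full_height_line_splits_block():
    from rownav import connected_components
    rows = np.zeros((20, 20), np.uint8)
    rows[2:18, 4:16] = 255
    edges = np.zeros_like(rows)
    edges[:, 9] = 255
    parts = connected_components(edge_cut(rows, edges))
    assert len(parts) == 2


def test_edge_cut_shape_mismatch():
    with pytest.raises(ValueError):
        edge_cut(np.zeros((4, 4), np.uint8), np.zeros((5, 4), np.uint8))
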
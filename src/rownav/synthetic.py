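"""Synthetic seedling-field frames with exact ground truth.

The generator emulates the imaging conditions of a camera-guided sprayer
in wide-narrow-row ("one film, six rows") sown cotton/maize/soybean:

* a pinhole camera 100 cm above flat ground, optical axis tilted 65 deg
  from the plumb line, 640 x 480 px frames;
* paired narrow rows (10 cm apart) of small-leaved seedlings on bright
  mulch-film strips, pairs separated by a 66 cm wide soil gap;
* perspective convergence plus canopy overlap that makes the two central
  rows adhere near the top of the image (controlled by ``adhesion_scale``);
* random missing seedlings (``miss_prob``) and rut-mark intervals where
  wheels crushed a row clean;
* sunny/cloudy illumination presets and specular reflections on the film.

Plants are drawn as clusters of green ellipses with darker rims.  The rims
matter: they are the leaf contours that the Canny stage later uses to cut
adhered rows apart, mirroring the intensity seams between touching leaves
of neighbouring real plants.

Every frame is a pure function of ``(scene, camera)``: the scene seed
fixes the frame bit-exactly, and the random draws are consumed in an
order independent of the camera's lateral position, so a drifting camera
in :func:`render_sequence` sees the *same* field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import draw as skdraw

from .errors import BehindCamera
from .navline import NavLine

# ---------------------------------------------------------------------------
# camera


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera over flat ground.

    Ground coordinates are centimetres in the camera's own frame: ``X``
    lateral (rightward positive), ``Y`` forward distance along the ground.
    ``tilt_deg`` is the angle between the optical axis and the plumb line.
    ``focal_px`` is not printed in any field protocol; the default makes
    the central narrow-row pair span roughly the middle third of the
    frame.
    """

    height_cm: float = 100.0
    tilt_deg: float = 65.0
    image_size: tuple[int, int] = (640, 480)  # (W, H)
    focal_px: float = 2400.0

    def __post_init__(self):
        if not (0 < self.tilt_deg < 90):
            raise ValueError("tilt_deg must lie strictly between 0 and 90")
        if self.focal_px <= 0 or self.height_cm <= 0:
            raise ValueError("focal_px and height_cm must be positive")

    @property
    def principal_point(self) -> tuple[float, float]:
        w, h = self.image_size
        return ((w - 1) / 2.0, (h - 1) / 2.0)

    def _trig(self):
        t = math.radians(self.tilt_deg)
        return math.sin(t), math.cos(t)

    def depth(self, y_cm):
        """Optical-axis depth of ground points at forward distance Y."""
        s, c = self._trig()
        return np.asarray(y_cm, dtype=np.float64) * s + self.height_cm * c

    def project(self, x_cm, y_cm):
        """Project ground points (cm) to pixel coordinates (u, v)."""
        s, c = self._trig()
        x = np.asarray(x_cm, dtype=np.float64)
        y = np.asarray(y_cm, dtype=np.float64)
        depth = y * s + self.height_cm * c
        if np.any(depth <= 0):
            raise BehindCamera("ground point projects from behind the camera")
        cx, cy = self.principal_point
        u = cx + self.focal_px * x / depth
        v = cy + self.focal_px * (self.height_cm * s - y * c) / depth
        return u, v

    def backproject(self, u, v):
        """Ground coordinates (cm) of pixels (u, v); rays must hit the ground."""
        s, c = self._trig()
        cx, cy = self.principal_point
        r = (np.asarray(v, dtype=np.float64) - cy) / self.focal_px
        denom = c + r * s
        if np.any(denom <= 0):
            raise BehindCamera("pixel ray points above the horizon")
        y = self.height_cm * (s - r * c) / denom
        depth = y * s + self.height_cm * c
        x = (np.asarray(u, dtype=np.float64) - cx) * depth / self.focal_px
        return x, y

    def px_per_cm_at(self, v: float) -> float:
        """Horizontal image scale (px/cm) at image row ``v``."""
        _, y = self.backproject(self.principal_point[0], v)
        return self.focal_px / float(self.depth(y))


def project_ground(camera: CameraModel, point):
    """Project one ground-plane point (X, Y) in cm to image (u, v) in px."""
    u, v = camera.project(point[0], point[1])
    return float(u), float(v)


# ---------------------------------------------------------------------------
# scene description

ILLUMINATION_PRESETS = {
    # gain scales all intensities; desat blends toward gray (flat light).
    "sunny": {"gain": 1.12, "desat": 0.0},
    "cloudy": {"gain": 0.85, "desat": 0.18},
}

CROP_LEAVES = {
    # aspect: leaf length/width ratio (length runs along the row);
    # n_leaves: ellipses per plant.
    "cotton": {"aspect": 1.4, "n_leaves": (8, 11)},
    "soybean": {"aspect": 1.8, "n_leaves": (8, 11)},
    "corn": {"aspect": 3.5, "n_leaves": (7, 10)},
}

_SOIL_RGB = np.array([125.0, 105.0, 82.0])
_MULCH_RGB = np.array([168.0, 170.0, 166.0])
_PLANT_RGB = np.array([62.0, 148.0, 58.0])
#: Mulch-film strip half-width beyond the narrow pair (cm).
_FILM_MARGIN_CM = 7.0


@dataclass(frozen=True)
class SyntheticScene:
    """Ground-truth geometry and degradation parameters of one frame.

    Spacings are ground centimetres.  ``rut_segments`` is a tuple of
    ``(row_index, (y0_cm, y1_cm))`` intervals wiped clean (row indices 0-5,
    left to right; the central pair is rows 2 and 3).
    ``lateral_offset_cm`` is the camera's lateral position relative to the
    central pair's centerline; ``adhesion_scale`` multiplies canopy size at
    the far end of the visible range (1 = no extra far-field overlap).
    """

    narrow_row_spacing: float = 10.0
    wide_row_spacing: float = 66.0
    plant_spacing: float = 9.5
    plant_radius: float = 2.5
    miss_prob: float = 0.0
    rut_segments: tuple = ()
    adhesion_scale: float = 1.6
    illumination: str = "sunny"
    mulch_reflectance: float = 0.25
    lateral_offset_cm: float = 0.0
    crop: str = "cotton"
    noise_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if min(self.narrow_row_spacing, self.wide_row_spacing,
               self.plant_spacing, self.plant_radius) <= 0:
            raise ValueError("spacings and plant radius must be positive")
        if not (0 <= self.miss_prob <= 1):
            raise ValueError("miss_prob must lie in [0, 1]")
        if self.adhesion_scale <= 0:
            raise ValueError("adhesion_scale must be positive")
        if self.illumination not in ILLUMINATION_PRESETS:
            raise ValueError(f"unknown illumination {self.illumination!r}")
        if self.crop not in CROP_LEAVES:
            raise ValueError(f"unknown crop {self.crop!r}")
        for seg in self.rut_segments:
            idx, (y0, y1) = seg
            if not (0 <= int(idx) <= 5) or y1 < y0:
                raise ValueError(f"bad rut segment {seg!r}")

    @property
    def row_offsets_cm(self) -> tuple[float, ...]:
        """World lateral positions of the six rows (central pair center = 0)."""
        pitch = self.wide_row_spacing + self.narrow_row_spacing
        half = self.narrow_row_spacing / 2.0
        return tuple(pc + s for pc in (-pitch, 0.0, pitch)
                     for s in (-half, half))


@dataclass(frozen=True)
class GroundTruth:
    """Exact reference for one rendered frame."""

    #: Projection of the ground-plane inter-row centerline.
    line: NavLine
    #: Horizontal image scale at the bottom image row.
    px_per_cm_bottom: float
    image_size: tuple[int, int]
    #: Camera-frame lateral position (cm) of the true centerline.
    centerline_x_cm: float
    #: Per-plant records: (row_index, world_x_cm, y_cm, status) with status
    #: one of "present", "missing", "rut".
    plants: tuple = field(default=(), repr=False)


# ---------------------------------------------------------------------------
# rendering helpers

def _visible_y_range(camera: CameraModel) -> tuple[float, float]:
    cx, _ = camera.principal_point
    w, h = camera.image_size
    _, y_near = camera.backproject(cx, h - 1)
    _, y_far = camera.backproject(cx, 0)
    return float(y_near), float(y_far)


def _plant_params(scene: SyntheticScene, rng: np.random.Generator,
                  y_lo: float, y_hi: float):
    """Draw all stochastic plant parameters in a camera-independent order.

    Each plant is a small cluster of leaf ellipses spread mostly *along*
    the row (machine-sown seedling rows read as near-continuous foliage
    strips broken only by genuinely missing plants); the cross-row reach
    is bounded by ``plant_radius`` so the inter-row gap stays visible.
    Leaf tuples are ``(off_along, off_cross, len_cm, width_cm, rot,
    color_jitter)``.
    """
    leaves = CROP_LEAVES[scene.crop]
    n_lo, n_hi = leaves["n_leaves"]
    aspect = leaves["aspect"]
    half_len = 0.7 * scene.plant_spacing
    plants = []
    y_positions = np.arange(math.floor(y_lo / scene.plant_spacing),
                            math.ceil(y_hi / scene.plant_spacing) + 1) \
        * scene.plant_spacing
    for row_idx, row_x in enumerate(scene.row_offsets_cm):
        for y0 in y_positions:
            jx = rng.normal(0.0, 0.15)
            jy = rng.normal(0.0, 1.0)
            missing = rng.random() < scene.miss_prob
            n_leaf = int(rng.integers(n_lo, n_hi + 1))
            leaf = []
            for _ in range(n_leaf):
                off_along = rng.uniform(-0.9, 0.9) * half_len
                off_cross = rng.normal(0.0, 0.04) * scene.plant_radius
                w_cm = scene.plant_radius * rng.uniform(0.96, 1.0)
                l_cm = min(w_cm * aspect * rng.uniform(0.85, 1.15),
                           1.1 * half_len)
                rot = rng.normal(0.0, 0.15)
                jitter = rng.normal(0.0, 10.0, 3)
                leaf.append((off_along, off_cross, l_cm, w_cm, rot, jitter))
            status = "present"
            if missing:
                status = "missing"
            else:
                for idx, (r0, r1) in scene.rut_segments:
                    if int(idx) == row_idx and r0 <= y0 + jy <= r1:
                        status = "rut"
                        break
            plants.append({"row": row_idx, "x": row_x + jx, "y": y0 + jy,
                           "status": status, "leaves": leaf})
    return plants


def _speck_params(scene: SyntheticScene, rng: np.random.Generator,
                  y_lo: float, y_hi: float):
    """Specular film-reflection patches (camera-independent draws)."""
    pitch = scene.wide_row_spacing + scene.narrow_row_spacing
    half = scene.narrow_row_spacing / 2.0 + _FILM_MARGIN_CM
    n = int(round(60 * scene.mulch_reflectance))
    specks = []
    for _ in range(n):
        pair = float(rng.choice((-pitch, 0.0, pitch)))
        x = pair + rng.uniform(-half, half)
        y = rng.uniform(y_lo, y_hi)
        r = rng.uniform(1.0, 4.0)
        gain = rng.uniform(1.2, 1.45)
        specks.append((x, y, r, gain))
    return specks


def _adhesion(scene: SyntheticScene, y: float,
              y_near: float, y_far: float) -> float:
    frac = np.clip((y - y_near) / max(y_far - y_near, 1e-9), 0.0, 1.0)
    return 1.0 + (scene.adhesion_scale - 1.0) * float(frac)


def render_frame(scene: SyntheticScene,
                 camera: CameraModel | None = None
                 ) -> tuple[np.ndarray, GroundTruth]:
    """Render one frame and its ground truth.

    Deterministic: the same (scene, camera) pair yields a bit-identical
    frame.
    """
    camera = camera if camera is not None else CameraModel()
    w, h = camera.image_size
    rng = np.random.default_rng(scene.seed)
    illum = ILLUMINATION_PRESETS[scene.illumination]
    gain, desat = illum["gain"], illum["desat"]
    y_near, y_far = _visible_y_range(camera)
    y_lo, y_hi = y_near - 15.0, y_far + 15.0
    d = scene.lateral_offset_cm

    def shade(rgb):
        rgb = np.asarray(rgb, dtype=np.float64) * gain
        return rgb * (1 - desat) + rgb.mean() * desat

    # --- background: soil with mulch-film strips under each row pair
    us, vs = np.meshgrid(np.arange(w, dtype=np.float64),
                         np.arange(h, dtype=np.float64))
    gx, _ = camera.backproject(us, vs)
    world_x = gx + d
    pitch = scene.wide_row_spacing + scene.narrow_row_spacing
    nearest_pair = np.round(world_x / pitch) * pitch
    on_film = np.abs(world_x - nearest_pair) <= (
        scene.narrow_row_spacing / 2.0 + _FILM_MARGIN_CM)
    img = np.where(on_film[..., None], shade(_MULCH_RGB), shade(_SOIL_RGB))

    # --- stochastic content (rng order independent of lateral offset)
    specks = _speck_params(scene, rng, y_lo, y_hi)
    plants = _plant_params(scene, rng, y_lo, y_hi)
    noise = rng.normal(0.0, scene.noise_sigma, (h, w, 3))

    # --- film reflections
    for x_w, y_w, r_cm, sgain in specks:
        xc = x_w - d
        depth = float(camera.depth(y_w))
        if depth <= 0:
            continue
        u, v = camera.project(xc, y_w)
        sx = camera.focal_px / depth
        sy = camera.focal_px * camera.height_cm / depth ** 2
        rr, cc = skdraw.ellipse(float(v), float(u), max(r_cm * sy, 1.0),
                                max(r_cm * sx, 1.0), shape=(h, w))
        img[rr, cc] = np.minimum(img[rr, cc] * sgain, 255.0)

    # --- plants, far first so near canopies overdraw
    plant_base = shade(_PLANT_RGB)
    for plant in sorted(plants, key=lambda p: -p["y"]):
        if plant["status"] != "present":
            continue
        xc, yc = plant["x"] - d, plant["y"]
        depth = float(camera.depth(yc))
        if depth <= 0:
            continue
        u, v = camera.project(xc, yc)
        if not (-60 <= u <= w + 60 and -60 <= v <= h + 60):
            continue
        sx = camera.focal_px / depth
        sy = camera.focal_px * camera.height_cm / depth ** 2
        scale = _adhesion(scene, yc, y_near, y_far)
        for off_along, off_cross, l_cm, w_cm, rot, jitter in plant["leaves"]:
            uc = u + off_cross * sx * scale
            vc = v + off_along * sy * scale
            ra = max(l_cm * sy * scale, 1.0)
            rc = max(w_cm * sx * scale, 1.0)
            color = np.clip(plant_base + jitter, 0, 255)
            # darker rim first, then the lighter interior: the ~1.5 px
            # contour left exposed is the leaf edge Canny will find
            rr, cc = skdraw.ellipse(vc, uc, ra, rc, shape=(h, w),
                                    rotation=rot)
            img[rr, cc] = color * 0.55
            ri = max(ra - 1.5, 0.5)
            ci = max(rc - 1.5, 0.5)
            rr, cc = skdraw.ellipse(vc, uc, ri, ci, shape=(h, w),
                                    rotation=rot)
            img[rr, cc] = color

    img = np.clip(img + noise, 0, 255).astype(np.uint8)

    # --- ground truth: projection of the inter-row centerline X = -d
    (u1, v1) = camera.project(-d, y_near)
    (u2, v2) = camera.project(-d, y_far)
    a = (float(u2) - float(u1)) / (float(v2) - float(v1))
    b = float(u1) - a * float(v1)
    truth = GroundTruth(
        line=NavLine(a=a, b=b, support=2),
        px_per_cm_bottom=camera.px_per_cm_at(h - 1),
        image_size=camera.image_size,
        centerline_x_cm=-d,
        plants=tuple((p["row"], p["x"], p["y"], p["status"]) for p in plants),
    )
    return img, truth


def broken_row_scene(seed: int, miss_prob: float = 0.2) -> SyntheticScene:
    """Degraded-field scenario: missing seedlings plus rut marks.

    Each central row carries a wheel-rut interval in the near field
    (168-178 cm forward distance, i.e. the bottom image band below the
    default ROI), mirroring the situation where rutted seedlings lie
    outside the region the line is fitted in.
    """
    return SyntheticScene(seed=seed, miss_prob=miss_prob,
                          rut_segments=((2, (168.0, 178.0)),
                                        (3, (168.0, 178.0))))


def adhesion_scene(seed: int, adhesion_scale: float = 2.4) -> SyntheticScene:
    """Forced far-field adhesion: canopies of the two central rows overlap
    near the top of the image and merge into a single thresholded domain."""
    return SyntheticScene(seed=seed, adhesion_scale=adhesion_scale)


def render_sequence(scene: SyntheticScene, camera: CameraModel | None = None,
                    n_frames: int = 1, drift: float = 0.0):
    """Frames of a camera sliding laterally by ``drift`` cm per frame.

    The field (plant layout, specks, noise) is identical across frames —
    only the camera moves — so the ground-truth line shifts accordingly.
    Returns ``(frames, truths)`` lists.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    frames, truths = [], []
    for i in range(n_frames):
        shifted = replace(scene,
                          lateral_offset_cm=scene.lateral_offset_cm + drift * i)
        frame, truth = render_frame(shifted, camera)
        frames.append(frame)
        truths.append(truth)
    return frames, truths
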
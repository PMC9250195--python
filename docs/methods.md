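# Methods

This note documents the models and the numerical choices behind
`rownav`: the detection pipeline for the inter-row navigation line of
double-row-sown seedling crops, the synthetic field generator used to
exercise it, and the evaluation conventions.

## The detection problem

In wide–narrow-row sowing (the "one film, six rows" machine-picked
cotton layout: paired rows ~10 cm apart, pairs separated by a ~66 cm
inter-pair gap, sown on plastic mulch film) a guidance camera looks
forward and down along the central pair. The navigation line is the
straight line through the soil gap between the two central narrow rows.
Two disturbances dominate at the seedling stage:

* **row adhesion** — under perspective the two rows converge toward the
  image top and their canopies appear to touch or merge;
* **row breakage** — missing seedlings (skips, failed germination,
  disease) and wheel-rut marks open along-row gaps, most visibly near
  the image bottom where the ground sampling is finest.

The pipeline resolves the conflict between these two: dilation strong
enough to bridge breaks aggravates adhesion, so bridging is done with a
vertically-acting element only, and adhesion is then removed by cutting
the dilated mask along detected leaf contours.

## Pipeline stages and parameters

| parameter | default | unit | role |
|---|---|---|---|
| `gaussian_radius` | 0.3 | px (σ) | Canny smoothing; 0.5 for maize (long narrow leaves produce excess edges at 0.3) |
| `canny_low/high` | automatic | gradient units | `high` = Otsu level of the gradient magnitude, `low = 0.4·high` |
| `se_shape`, `se_style` | (21, 7), vertical bar | px | bridging element: 21 rows tall, active center column |
| `dilation_iterations` | 5 | — | total vertical growth 50 px per side |
| `min_component_area` | 50 | px | noise-domain removal (area = 50 survives) |
| `roi_margin` | 50 | px | horizontal ROI extension beyond the central pair |
| `roi_band` | (0.25, 0.75) | fraction of H | vertical ROI: below the adhesion zone, above the breakage zone |
| `max_hole_area` | 1000 | px | inverted domains smaller than this are edge-cut debris |
| `min_class_separation` | 40 | gray levels | vegetation-presence guard (see below) |

Design choices that were genuinely open:

* **ExG range handling.** The raw index 2G − R − B spans −510..510; it is
  clamped to [0, 255] rather than rescaled, so red/blue-heavy background
  (soil, mulch, specular film reflections) lands at exactly 0 and only
  green foliage is highlighted. An affine rescale is available behind
  `exg_rescale` for diagnostic use.
* **Structuring-element footprint.** A full 7-wide rectangle iterated
  five times widens every row by 15 px per side, which measurably fills
  the inter-row corridor and merges the central pair — the opposite of
  what bridging is for. The default element is therefore the active
  center column of the 21 × 7 footprint: the expansion grows masks
  vertically and leaves row width untouched. The full rectangle remains
  available (`se_style: rect`).
* **Stage order.** The edge cut is applied *before* central-pair
  selection. Under adhesion the two central rows form a single connected
  domain; selecting a left and a right row is only meaningful after the
  cut has separated them.
* **Vegetation-presence guard.** A frame containing no vegetation still
  yields an Otsu split — of mulch from soil, a few gray levels apart —
  and without a guard the pipeline would happily fit a line to the film
  edge. Measured separations are ≤ 19 gray levels for soil/mulch-only
  frames and ≥ 109 for frames with seedling rows, so the guard
  (default 40) sits an order of magnitude from both.
* **Line parameterization.** The gap runs roughly vertically, so x is
  regressed on y (`x = a·y + b`); y-on-x would be ill-conditioned. All
  gap pixels are used as fit points, which weights wide gap regions more;
  a one-midpoint-per-row variant is available (`fit_points:
  row_midpoints`).
* **Ideal pose for the lateral error.** The "ideal position" in the
  lateral-error formula is not operationally defined by field practice
  (it is whatever the experienced operator judges right). The package's
  convention: the true (ground-truth) line's intersection with the bottom
  image row, mapped to the ground plane; the actual pose is the detected
  line's. This is a documented convention, not a claim about the original
  field trials.
* **Curvature per frame vs. per sequence.** A single frame yields a
  straight line (ρ = 0); `path_kinematics` applies to across-frame
  trajectories or user-supplied paths, computing ρ, ρ̇ and the yaw-rate
  prediction ω_p = v·ρ. Analytic inputs are differentiated by central
  differences (step 1e-3 by default); sampled inputs via `np.gradient`
  (≥ 5 samples required).

### Degenerate inputs and tie-breaks

Single-intensity images raise `DegenerateHistogram`; Otsu ties go to the
smallest threshold. Component labels are assigned in raster order of each
domain's first pixel (scipy's labeling), so results are deterministic;
central-pair ties go to the larger area, then the smaller label. Fit
points must span two distinct image rows (`DegenerateFit` otherwise).
Every stage failure is caught by `detect_frame` and encoded in the result
status — a valid frame never raises.

## The synthetic field generator

`rownav.synthetic` renders frames from a flat-ground pinhole model:
camera 100 cm above ground, optical axis tilted 65° from the plumb line,
640 × 480 px. The focal length is not part of any published field
protocol; the default (2400 px) frames the central pair across roughly
the middle third of the image, matching typical guidance-camera
compositions. Scene geometry defaults: narrow spacing 10 cm, wide
spacing 66 cm, in-row plant spacing 9.5 cm — the standard machine-picked
cotton layout.

Plants are clusters of green leaf ellipses with darker rims, spread
mostly *along* the row so that a healthy row reads as a near-continuous
foliage strip with a tightly bounded cross-row reach (`plant_radius`,
default 2.5 cm). This emulates a uniformly emerged machine-sown stand;
the rims matter because they are the intensity seams between touching
leaves that the Canny stage later cuts along. Degradations are explicit:

* `miss_prob` — independent per-plant absence (seeder skips, failed
  germination);
* `rut_segments` — along-row intervals wiped clean (wheel damage);
* `adhesion_scale` — canopy-size multiplier growing linearly toward the
  far field, standing in for the 3-D canopy overlap that a flat-blob
  renderer cannot produce geometrically (default 1.6: near-touching at
  the image top; 2.4 in the forced-adhesion scenario: merged);
* illumination presets (`sunny`/`cloudy`: gain and desaturation) and
  specular reflection patches on the mulch film;
* per-pixel Gaussian sensor noise (σ = 6).

Rendering is a pure function of (scene, camera): one seeded generator
drives all randomness, and the draws are consumed in a camera-independent
order, so a laterally drifting camera (`render_sequence`) observes the
same field. The ground-truth line is the exact projection of the
ground-plane centerline of the central pair.

**What passing on this generator does and does not show.** The generator
reproduces the *phenomenology* the pipeline is built against — perspective
convergence, far-field adhesion, within-row breaks, film reflections,
illumination changes — with known ground truth. It does not reproduce
textured leaves, shadows cast across rows, weeds, wind blur, or the
canopy irregularity of a stressed stand; accuracy figures measured here
characterize the algorithm under controlled degradation, not field
performance.

## Evaluation conventions

A detection is scored at the bottom image row: signed lateral offset
(detected minus true line position, in px and — through the camera's
ground scale at that row — in cm) and unsigned heading error
(|arctan a_det − arctan a_true|, degrees, folded into [0, 90]). A frame
is *correct* iff detection succeeded and both deviations are inside the
tolerances; the default gate is pixel-space (5 px, 2°) because a
cm-space gate depends on the configured focal length. The tolerance gate
replaces the human judgment used in field practice. Sequence summaries
report the accuracy rate 100·(total − error)/total and *sample* (n−1)
standard deviations of the deviations over frames whose detection
succeeded.

## Problem sizes

The test suite and `scripts/acceptance.py` measure: 40 pristine frames
(median recovery error), 200 forced-adhesion frames (separation rate),
200 broken-row frames at miss probability 0.2 with ruts below the ROI
band (accuracy rate, deviation stds), and 20 seeds × 3 frames per
missing-seedling level for the monotonicity check. At these sizes the
statistics are stable to a few tenths of a percent while a full run
stays in the minutes range on one CPU.

## Known limitations

* Straight rows only: a single least-squares line cannot follow bent
  sowing lines; curved-row support would need a segment-wise or
  polynomial fit.
* The gap domain is taken whole: a row break that connects the corridor
  to the outer background inside the ROI skews the fit — this is the
  dominant residual failure at high missing-seedling rates, and it
  mirrors the documented field failure cause (missing seedlings / rut
  marks inside the ROI).
* The vegetation guard assumes ExG-dark backgrounds; green weeds between
  rows (absent at the seedling stage in mulched fields) would defeat
  both the guard and the gap extraction.
* Frame-independent processing: no temporal smoothing across video
  frames, by design.
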
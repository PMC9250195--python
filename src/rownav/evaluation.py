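"""Scoring detections against ground truth.

A detected navigation line is compared with the true inter-row centerline
at the bottom image row (signed lateral offset, converted to ground
centimetres through the camera scale) and in heading (angle between the
two lines).  A frame counts as correct when detection succeeded and both
deviations fall inside configured tolerances — a quantitative stand-in
for the field practice of having experienced personnel judge each frame.

Sequence summaries mirror the usual field-trial table: total frames,
error frames, accuracy rate and the sample standard deviations of the
lateral and heading deviations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .navline import DetectionResult, NavLine
from .synthetic import GroundTruth


@dataclass(frozen=True)
class FrameScore:
    """Deviations of one detected frame from its ground truth."""

    lateral_offset_px: float
    lateral_offset_cm: float
    heading_error_deg: float
    correct: bool
    status: str


@dataclass(frozen=True)
class SequenceSummary:
    """Accuracy and deviation statistics over a frame sequence."""

    total_frames: int
    error_frames: int
    accuracy_rate: float
    lateral_std_cm: float
    heading_std_deg: float
    causes: dict

    def to_dict(self) -> dict:
        return {
            "total_frames": self.total_frames,
            "error_frames": self.error_frames,
            "accuracy_rate": self.accuracy_rate,
            "lateral_std_cm": self.lateral_std_cm,
            "heading_std_deg": self.heading_std_deg,
            "causes": dict(self.causes),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def format_table(self, video_id: str = "sequence") -> str:
        """Plain-text row in the style of a field-trial results table."""
        causes = "/".join(sorted(self.causes)) if self.causes else "-"
        header = (f"{'Video ID':<16}{'Total frames':>14}{'Error frames':>14}"
                  f"{'Accuracy rate (%)':>19}  Cause of the error")
        row = (f"{video_id:<16}{self.total_frames:>14}{self.error_frames:>14}"
               f"{self.accuracy_rate:>19.1f}  {causes}")
        return header + "\n" + row


def heading_error_deg(a_detected: float, a_true: float) -> float:
    """Unsigned angle (deg) between two lines ``x = a*y + b``; in [0, 90]."""
    diff = abs(math.degrees(math.atan(a_detected) - math.atan(a_true)))
    return min(diff, 180.0 - diff)


def score_frame(result: DetectionResult, truth: GroundTruth,
                *, lateral_tol_px: float = 5.0, heading_tol_deg: float = 2.0,
                lateral_tol_cm: float | None = None) -> FrameScore:
    """Score one frame.

    The lateral offset is the signed difference (detected minus true) of
    the line x-positions at the bottom image row, in px and in ground cm.
    The frame is correct iff detection succeeded and the absolute lateral
    offset and heading error are inside the tolerances (the cm gate is
    applied only when ``lateral_tol_cm`` is given).
    """
    if not result.ok or result.line is None:
        return FrameScore(math.nan, math.nan, math.nan, False, result.status)
    y_bottom = truth.image_size[1] - 1
    lat_px = result.line.x_at(y_bottom) - truth.line.x_at(y_bottom)
    lat_cm = lat_px / truth.px_per_cm_bottom
    heading = heading_error_deg(result.line.a, truth.line.a)
    correct = abs(lat_px) <= lateral_tol_px and heading <= heading_tol_deg
    if lateral_tol_cm is not None:
        correct = correct and abs(lat_cm) <= lateral_tol_cm
    return FrameScore(float(lat_px), float(lat_cm), float(heading),
                      bool(correct), result.status)


def summarize(scores: list[FrameScore],
              causes: list[str] | None = None) -> SequenceSummary:
    """Accuracy rate and deviation statistics over a non-empty score list.

    Standard deviations are sample (n-1) deviations over the frames whose
    detection succeeded; NaN when fewer than two such frames exist.
    ``causes`` optionally tags each frame with a scenario factor; the
    histogram counts tags (or, absent tags, statuses) of incorrect frames.
    """
    if not scores:
        raise ValueError("cannot summarize an empty score list")
    if causes is not None and len(causes) != len(scores):
        raise ValueError("causes must match scores in length")
    total = len(scores)
    errors = sum(1 for s in scores if not s.correct)
    ok = [s for s in scores if s.status == "ok"]
    if len(ok) >= 2:
        lat_std = float(np.std([s.lateral_offset_cm for s in ok], ddof=1))
        head_std = float(np.std([s.heading_error_deg for s in ok], ddof=1))
    else:
        lat_std = head_std = math.nan
    hist: dict[str, int] = {}
    for i, s in enumerate(scores):
        if s.correct:
            continue
        tag = causes[i] if causes is not None else (
            s.status if s.status != "ok" else "off_tolerance")
        hist[tag] = hist.get(tag, 0) + 1
    return SequenceSummary(
        total_frames=total,
        error_frames=errors,
        accuracy_rate=100.0 * (total - errors) / total,
        lateral_std_cm=lat_std,
        heading_std_deg=head_std,
        causes=hist,
    )


def score_from_records(result_rec: dict, truth_rec: dict,
                       **tol) -> FrameScore:
    """Score from JSON records as written by the CLI."""
    line = None
    if result_rec.get("line"):
        ln = result_rec["line"]
        line = NavLine(a=ln["a"], b=ln["b"], support=ln["support"])
    result = DetectionResult(status=result_rec["status"], line=line)
    tl = truth_rec["line"]
    truth = GroundTruth(
        line=NavLine(a=tl["a"], b=tl["b"], support=tl.get("support", 2)),
        px_per_cm_bottom=truth_rec["px_per_cm_bottom"],
        image_size=tuple(truth_rec["image_size"]),
        centerline_x_cm=truth_rec.get("centerline_x_cm", 0.0),
    )
    return score_frame(result, truth, **tol)
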
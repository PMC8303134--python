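"""Graf angle geometry.

A standard-plane coronal hip ultrasound is measured with three lines:

* the *baseline* along the vertical ilium,
* the *bony roof line* from the lower edge of the ilium to the acetabular
  bone edge (the bony rim), and
* the *cartilage roof line* from the bone edge to the tip of the labrum.

The alpha angle (baseline vs. bony roof) grades the bony coverage of the
femoral head; alpha >= 60 deg is a normal (Graf type I) hip.  The beta angle
(baseline vs. cartilage roof) grades the cartilaginous coverage.  A third
*check angle* — the tilt of the iliac wing relative to the image vertical —
is used as an image-appropriateness measure: a valid standard plane shows
the ilium near-vertical.

Coordinate frame: x grows rightward, y grows *downward* (raster convention),
0-based pixel indices, sub-pixel coordinates allowed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateLineError, ValidationError

__all__ = [
    "Point2D",
    "LandmarkSet",
    "GrafMeasurement",
    "angle_between_lines",
    "compute_check_angle",
    "compute_alpha",
    "compute_beta",
    "classify_graf",
    "measure",
    "ALPHA_CUTOFF_DEG",
]

#: Graf type-I threshold on the alpha angle (degrees, boundary inclusive).
ALPHA_CUTOFF_DEG = 60.0


@dataclass(frozen=True)
class Point2D:
    """A sub-pixel image point; y increases downward."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"point coordinates must be finite, got ({self.x}, {self.y})")


@dataclass(frozen=True)
class LandmarkSet:
    """The five anatomical points from which all Graf angles derive.

    ``check_upper`` and ``triradiate`` are the two check-angle points on the
    iliac wing; ``triradiate`` doubles as the tri-radiate cartilage point that
    anchors the distal baseline.  ``lower_ilium`` and ``bone_edge`` span the
    bony roof line; ``bone_edge`` and ``labrum_end`` span the cartilage roof
    line.
    """

    check_upper: Point2D
    triradiate: Point2D
    lower_ilium: Point2D
    bone_edge: Point2D
    labrum_end: Point2D

    def __post_init__(self) -> None:
        for a, b in (
            ("check_upper", "triradiate"),
            ("lower_ilium", "bone_edge"),
            ("bone_edge", "labrum_end"),
        ):
            if getattr(self, a) == getattr(self, b):
                raise ValidationError(f"landmarks {a} and {b} must be distinct")

    def points(self) -> dict[str, Point2D]:
        return {
            "check_upper": self.check_upper,
            "triradiate": self.triradiate,
            "lower_ilium": self.lower_ilium,
            "bone_edge": self.bone_edge,
            "labrum_end": self.labrum_end,
        }


@dataclass(frozen=True)
class GrafMeasurement:
    """One rater's angle readings plus the 60-degree normal/abnormal call."""

    check_deg: float
    alpha_deg: float
    beta_deg: float
    graf_call: str  # "normal" | "abnormal"


def angle_between_lines(a1: Point2D, a2: Point2D, b1: Point2D, b2: Point2D) -> float:
    """Unsigned minimal angle, in degrees in [0, 90], between two undirected lines.

    Symmetric both in the order of the two lines and in the order of the
    points within each line.

    Raises
    ------
    DegenerateLineError
        If either point pair is coincident.
    """
    ux, uy = a2.x - a1.x, a2.y - a1.y
    vx, vy = b2.x - b1.x, b2.y - b1.y
    nu = math.hypot(ux, uy)
    nv = math.hypot(vx, vy)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateLineError("coincident endpoints do not define a line")
    c = abs(ux * vx + uy * vy) / (nu * nv)
    return math.degrees(math.acos(min(1.0, c)))


def compute_check_angle(ls: LandmarkSet) -> float:
    """Signed tilt of the iliac wing from the image vertical, in (-90, 90].

    Zero when the wing (check_upper -> triradiate) is exactly vertical;
    positive when the distal (deeper, larger-y) end is rotated toward +x.
    """
    dx = ls.triradiate.x - ls.check_upper.x
    dy = ls.triradiate.y - ls.check_upper.y
    if dx == 0.0 and dy == 0.0:
        raise DegenerateLineError("check points are coincident")
    if dy < 0.0:  # orient the wing so its distal end is the larger-y end
        dx, dy = -dx, -dy
    if dy == 0.0:
        return 90.0  # horizontal wing: convention maps both signs to +90
    return math.degrees(math.atan2(dx, dy))


def compute_alpha(ls: LandmarkSet) -> float:
    """Alpha angle: baseline vs. bony roof line (lower_ilium -> bone_edge)."""
    return angle_between_lines(ls.check_upper, ls.triradiate, ls.lower_ilium, ls.bone_edge)


def compute_beta(ls: LandmarkSet) -> float:
    """Beta angle: baseline vs. cartilage roof line (bone_edge -> labrum_end)."""
    return angle_between_lines(ls.check_upper, ls.triradiate, ls.bone_edge, ls.labrum_end)


def classify_graf(alpha_deg: float, cutoff_deg: float = ALPHA_CUTOFF_DEG) -> str:
    """Dichotomous Graf call: ``"normal"`` iff alpha >= cutoff (inclusive).

    The inclusive boundary follows the Graf type-I definition (alpha of at
    least 60 degrees is a mature hip).
    """
    if not (0.0 <= alpha_deg <= 90.0):
        raise ValidationError(f"alpha angle must lie in [0, 90] degrees, got {alpha_deg}")
    return "normal" if alpha_deg >= cutoff_deg else "abnormal"


def measure(ls: LandmarkSet, cutoff_deg: float = ALPHA_CUTOFF_DEG) -> GrafMeasurement:
    """Compute all three angles and the Graf call from one landmark set."""
    alpha = compute_alpha(ls)
    return GrafMeasurement(
        check_deg=compute_check_angle(ls),
        alpha_deg=alpha,
        beta_deg=compute_beta(ls),
        graf_call=classify_graf(alpha, cutoff_deg),
    )
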
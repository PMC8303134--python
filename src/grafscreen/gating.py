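"""Two-criteria image triage and the detectability / check-angle tables.

An image enters the Graf-angle comparison only if it passes two gates:

1. **Detectability** — both raters (AI system and human reader) can see all
   key anatomical structures and their points.
2. **Check angle** — both raters measure an iliac-wing tilt within +/-5
   degrees of vertical, i.e. the image is an acceptable standard plane.

Images passing both are *appropriate*; detectable images failing the second
gate are *inappropriate (check angle)*; everything else is *fail detection*.
The module also builds the two summary tables the screening study reports:
per-rater detectability counts and the 2x2 cross-tabulation of the two
raters' check-angle gates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import ValidationError
from .geometry import GrafMeasurement

__all__ = [
    "CHECK_TOLERANCE_DEG",
    "RaterReading",
    "PairedReading",
    "TriageLabel",
    "ContingencyTable2x2",
    "DetectionTable",
    "check_gate",
    "triage",
    "tabulate_detection",
    "tabulate_check",
]

#: Appropriateness tolerance on the absolute check angle (degrees, inclusive).
CHECK_TOLERANCE_DEG = 5.0


@dataclass(frozen=True)
class RaterReading:
    """One rater's view of one image: a detectability flag and, when
    detectable, the angle measurement."""

    detectable: bool
    measurement: Optional[GrafMeasurement]

    def __post_init__(self) -> None:
        if self.detectable and self.measurement is None:
            raise ValidationError("a detectable reading must carry a measurement")
        if not self.detectable and self.measurement is not None:
            raise ValidationError("an undetectable reading cannot carry a measurement")


@dataclass(frozen=True)
class PairedReading:
    """The (AI, human) reading pair for one image — the unit of all
    agreement statistics."""

    image_id: str
    ai: RaterReading
    human: RaterReading


class TriageLabel(enum.Enum):
    APPROPRIATE = "appropriate"
    INAPPROPRIATE_CHECK_ANGLE = "inappropriate_check_angle"
    FAIL_DETECTION = "fail_detection"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cross-tabulation of the two raters' check-angle gates.

    ``a``: both OK; ``b``: AI OK / human error; ``c``: AI error / human OK;
    ``d``: both error.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def column_percentages(self) -> dict[str, float]:
        """AI-gate percentages within each human-gate column, to 1 decimal."""
        ok_col = self.a + self.c
        err_col = self.b + self.d
        out = {}
        if ok_col:
            out["ai_ok_given_human_ok"] = round(100.0 * self.a / ok_col, 1)
            out["ai_error_given_human_ok"] = round(100.0 * self.c / ok_col, 1)
        if err_col:
            out["ai_ok_given_human_error"] = round(100.0 * self.b / err_col, 1)
            out["ai_error_given_human_error"] = round(100.0 * self.d / err_col, 1)
        return out


def check_gate(check_deg: float, tolerance: float = CHECK_TOLERANCE_DEG) -> bool:
    """True (OK) iff |check_deg| <= tolerance; the boundary counts as OK."""
    return abs(check_deg) <= tolerance


def triage(pr: PairedReading, tolerance: float = CHECK_TOLERANCE_DEG) -> TriageLabel:
    """Assign the three-way appropriateness label to one paired reading."""
    if not (pr.ai.detectable and pr.human.detectable):
        return TriageLabel.FAIL_DETECTION
    if check_gate(pr.ai.measurement.check_deg, tolerance) and check_gate(
        pr.human.measurement.check_deg, tolerance
    ):
        return TriageLabel.APPROPRIATE
    return TriageLabel.INAPPROPRIATE_CHECK_ANGLE


@dataclass(frozen=True)
class DetectionTable:
    """Per-rater and joint detectability counts over a cohort."""

    n: int
    human_detectable: int
    ai_detectable: int
    commonly_detectable: int

    @property
    def fail_detection(self) -> int:
        return self.n - self.commonly_detectable

    def percentages(self) -> dict[str, float]:
        """All counts as percentages of cohort size, to 1 decimal."""
        return {
            "human_detectable": round(100.0 * self.human_detectable / self.n, 1),
            "human_undetectable": round(100.0 * (self.n - self.human_detectable) / self.n, 1),
            "ai_detectable": round(100.0 * self.ai_detectable / self.n, 1),
            "ai_undetectable": round(100.0 * (self.n - self.ai_detectable) / self.n, 1),
            "commonly_detectable": round(100.0 * self.commonly_detectable / self.n, 1),
            "fail_detection": round(100.0 * self.fail_detection / self.n, 1),
        }


def tabulate_detection(cohort: Sequence[PairedReading]) -> DetectionTable:
    """Detectability table (first triage criterion) over a cohort."""
    if len(cohort) == 0:
        raise ValidationError("cohort must be non-empty")
    human = sum(pr.human.detectable for pr in cohort)
    ai = sum(pr.ai.detectable for pr in cohort)
    common = sum(pr.ai.detectable and pr.human.detectable for pr in cohort)
    return DetectionTable(
        n=len(cohort), human_detectable=human, ai_detectable=ai, commonly_detectable=common
    )


def tabulate_check(
    cohort: Iterable[PairedReading], tolerance: float = CHECK_TOLERANCE_DEG
) -> ContingencyTable2x2:
    """Check-angle 2x2 table over commonly-detectable paired readings.

    Raises if any reading is undetectable by either rater: the second
    criterion is only defined on the commonly-detectable subset.
    """
    a = b = c = d = 0
    for pr in cohort:
        if not (pr.ai.detectable and pr.human.detectable):
            raise ValidationError(
                f"reading {pr.image_id} is not detectable by both raters"
            )
        ai_ok = check_gate(pr.ai.measurement.check_deg, tolerance)
        hu_ok = check_gate(pr.human.measurement.check_deg, tolerance)
        if ai_ok and hu_ok:
            a += 1
        elif ai_ok:
            b += 1
        elif hu_ok:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a=a, b=b, c=c, d=d)
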
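"""Classical two-stage multi-detection: structures -> stage-1 image -> keypoints.

The screening pipeline's detector has a fixed contract regardless of how it
is realised: given a grayscale standard-plane image it must (stage 1)
segment the ilium, acetabular roof and labrum and render them as a
white-on-black composite, then (stage 2) extract the five anatomical
keypoints from which the check/alpha/beta angles are computed.  This module
is the deterministic classical realisation — intensity thresholding,
connected components and geometric assignment rules — which serves both as
the desk-scale detector and as the reference behaviour for the trainable
variant in :mod:`grafscreen.neural`.

Failure is data, not an exception: an image in which the three structures
cannot all be found with sufficient contrast yields a result with
``detectable=False``, mirroring how unreadable clinical images are triaged
rather than crashed on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure

from .errors import MissingLandmarkError, ValidationError
from .geometry import LandmarkSet, Point2D

__all__ = [
    "StructureMaskSet",
    "DetectionResult",
    "segment_structures",
    "masks_to_stage1",
    "extract_keypoints",
    "detect",
    "DEFAULT_THRESHOLD_QUANTILE",
    "DEFAULT_CONFIDENCE_MIN",
]

STRUCTURES = ("ilium", "acetabulum", "labrum")

#: Default intensity quantile separating candidate bone from soft tissue.
DEFAULT_THRESHOLD_QUANTILE = 0.85
#: Minimum per-structure contrast confidence for a detectable result.
DEFAULT_CONFIDENCE_MIN = 0.5

_MIN_COMPONENT_AREA = 40


@dataclass
class StructureMaskSet:
    """Binary mask and contrast confidence per anatomical structure.

    Confidence is the Michelson contrast of the component against the
    background, (m - b)/(m + b) clipped to [0, 1]; it is invariant to the
    global brightness factor of the acquisition.
    """

    ilium: np.ndarray
    acetabulum: np.ndarray
    labrum: np.ndarray
    confidence: dict[str, float]

    def __post_init__(self) -> None:
        shapes = {self.ilium.shape, self.acetabulum.shape, self.labrum.shape}
        if len(shapes) != 1:
            raise ValidationError("structure masks must share image dimensions")
        for k, v in self.confidence.items():
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"confidence[{k}] must lie in [0, 1], got {v}")

    def mask(self, name: str) -> np.ndarray:
        return getattr(self, name)

    @property
    def is_complete(self) -> bool:
        return all(self.mask(s).any() for s in STRUCTURES)

    @classmethod
    def empty(cls, shape: Tuple[int, int]) -> "StructureMaskSet":
        z = np.zeros(shape, dtype=bool)
        return cls(ilium=z.copy(), acetabulum=z.copy(), labrum=z.copy(),
                   confidence={s: 0.0 for s in STRUCTURES})


@dataclass
class DetectionResult:
    """Detector output: masks, landmarks when extractable, detectability flag."""

    masks: StructureMaskSet
    landmarks: Optional[LandmarkSet]
    detectable: bool

    def __post_init__(self) -> None:
        if self.detectable and self.landmarks is None:
            raise ValidationError("a detectable result must carry landmarks")


def _threshold(image: np.ndarray, threshold_quantile: float) -> np.ndarray:
    """Foreground candidates: pixels above max(quantile, Otsu) threshold.

    The quantile alone under-thresholds speckled backgrounds (it marks a
    fixed pixel fraction regardless of contrast); Otsu alone has no notion
    of the expected bone fraction.  Taking the larger of the two keeps the
    quantile as the tuning knob while staying robust, and makes re-running
    the detector on its own binary stage-1 output idempotent.  Smoothing is
    skipped for binary inputs, which carry no speckle to suppress.
    """
    img = np.asarray(image, dtype=float)
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=bool)
    binary_input = np.isin(np.unique(image), (0, 255)).all()
    smooth = img if binary_input else ndi.gaussian_filter(img, 1.0)
    tq = float(np.quantile(smooth, threshold_quantile))
    totsu = float(filters.threshold_otsu(smooth))
    return smooth > max(tq, totsu)


def _principal_axis(coords: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Mean point and unit principal direction (oriented toward +y) of an
    (N, 2) array of (x, y) pixel coordinates."""
    mean = coords.mean(axis=0)
    centered = coords - mean
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt[0]
    if v[1] < 0 or (v[1] == 0 and v[0] < 0):
        v = -v
    return mean, v


def _axis_endpoints(coords: np.ndarray, band: float = 1.5):
    """Sub-pixel endpoints of a component along its principal axis.

    Each endpoint is the centroid of the pixels whose axial projection lies
    within ``band`` pixels of the extreme — the centroid refinement that
    gives sub-pixel keypoints.
    Returns (low_end, high_end, axis_dir); high_end has the larger
    projection onto the +y-oriented axis.
    """
    mean, v = _principal_axis(coords)
    proj = (coords - mean) @ v
    lo = coords[proj <= proj.min() + band].mean(axis=0)
    hi = coords[proj >= proj.max() - band].mean(axis=0)
    return lo, hi, v


def _coords_xy(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    return np.column_stack([xs, ys]).astype(float)


def _point_line_distance(pts: np.ndarray, origin: np.ndarray, direction: np.ndarray):
    d = pts - origin
    return np.abs(d[:, 0] * direction[1] - d[:, 1] * direction[0])


def segment_structures(
    image: np.ndarray, threshold_quantile: float = DEFAULT_THRESHOLD_QUANTILE
) -> StructureMaskSet:
    """Segment ilium / acetabular roof / labrum from a grayscale image.

    Thresholded connected components are assigned by geometry: the most
    elongated near-vertical component is the ilium; of the rest, the
    component nearest the ilium's distal end is the acetabular roof, and
    the component nearest the roof's lateral (bony-rim) end is the labrum.
    An incomplete result (fewer than three qualifying components) is
    returned with empty masks and zero confidences, never raised.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValidationError("expected a 2-D grayscale image")
    empty = StructureMaskSet.empty(img.shape)
    bw = _threshold(img, threshold_quantile)
    if not bw.any():
        return empty
    labels = measure.label(bw, connectivity=2)

    comps = []
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        if mask.sum() < _MIN_COMPONENT_AREA:
            bw[mask] = False  # speckle blob: exclude from foreground
            continue
        coords = _coords_xy(mask)
        mean, v = _principal_axis(coords)
        proj = (coords - mean) @ v
        comps.append({
            "mask": mask,
            "coords": coords,
            "mean": mean,
            "dir": v,
            "extent": float(proj.max() - proj.min()),
        })
    if len(comps) < 3:
        return empty

    # Ilium: longest component whose axis is within 50 degrees of vertical.
    vertical = [c for c in comps if abs(c["dir"][1]) >= np.cos(np.radians(50.0))]
    if not vertical:
        return empty
    ilium = max(vertical, key=lambda c: c["extent"])
    rest = [c for c in comps if c is not ilium]
    _, distal, _ = _axis_endpoints(ilium["coords"])
    acet = min(rest, key=lambda c: np.linalg.norm(c["mean"] - distal))
    rest = [c for c in rest if c is not acet]
    e1, e2, _ = _axis_endpoints(acet["coords"])
    # Bony-rim end of the roof = endpoint farther from the ilium axis line.
    d1 = _point_line_distance(e1[None, :], ilium["mean"], ilium["dir"])[0]
    d2 = _point_line_distance(e2[None, :], ilium["mean"], ilium["dir"])[0]
    rim = e1 if d1 >= d2 else e2
    labrum = min(rest, key=lambda c: np.linalg.norm(c["mean"] - rim))

    chosen = {"ilium": ilium, "acetabulum": acet, "labrum": labrum}
    bg = img[~bw]
    bg_mean = float(bg.mean()) if bg.size else 0.0
    confidence = {}
    for name, c in chosen.items():
        m = float(img[c["mask"]].mean())
        denom = m + bg_mean
        confidence[name] = float(np.clip((m - bg_mean) / denom, 0.0, 1.0)) if denom > 0 else 0.0
    return StructureMaskSet(
        ilium=chosen["ilium"]["mask"],
        acetabulum=chosen["acetabulum"]["mask"],
        labrum=chosen["labrum"]["mask"],
        confidence=confidence,
    )


def masks_to_stage1(masks: StructureMaskSet) -> np.ndarray:
    """Stage-1 composite: union of the structure masks as white (255) on
    black (0), uint8."""
    union = masks.ilium | masks.acetabulum | masks.labrum
    return np.where(union, 255, 0).astype(np.uint8)


def extract_keypoints(masks: StructureMaskSet) -> LandmarkSet:
    """Five sub-pixel keypoints from a complete structure mask set.

    check_upper / triradiate: proximal and distal principal-axis endpoints
    of the ilium band.  lower_ilium / bone_edge: roof-wedge endpoints, the
    one nearer the ilium axis being the lower edge of the ilium and the
    farther one the bony rim.  labrum_end: the labrum pixel set's distal
    tip, taken as the extreme projection along the bony-rim-to-labrum
    direction with centroid refinement.
    """
    for s in STRUCTURES:
        if not masks.mask(s).any():
            raise MissingLandmarkError(f"{s} mask is empty")
    il = _coords_xy(masks.ilium)
    check_upper, triradiate, il_dir = _axis_endpoints(il)
    il_mean = il.mean(axis=0)

    ac = _coords_xy(masks.acetabulum)
    e1, e2, _ = _axis_endpoints(ac)
    d1 = _point_line_distance(e1[None, :], il_mean, il_dir)[0]
    d2 = _point_line_distance(e2[None, :], il_mean, il_dir)[0]
    lower_ilium, bone_edge = (e1, e2) if d1 <= d2 else (e2, e1)

    lb = _coords_xy(masks.labrum)
    zdir = lb.mean(axis=0) - bone_edge
    norm = np.linalg.norm(zdir)
    if norm == 0:
        raise MissingLandmarkError("labrum coincides with the bony rim")
    zdir /= norm
    proj = (lb - bone_edge) @ zdir
    labrum_end = lb[proj >= proj.max() - 1.5].mean(axis=0)

    def pt(v: np.ndarray) -> Point2D:
        return Point2D(float(v[0]), float(v[1]))

    return LandmarkSet(
        check_upper=pt(check_upper),
        triradiate=pt(triradiate),
        lower_ilium=pt(lower_ilium),
        bone_edge=pt(bone_edge),
        labrum_end=pt(labrum_end),
    )


def detect(
    image: np.ndarray,
    threshold_quantile: float = DEFAULT_THRESHOLD_QUANTILE,
    confidence_min: float = DEFAULT_CONFIDENCE_MIN,
) -> DetectionResult:
    """Full two-stage detection on one grayscale image.

    Detectable iff all three structures segment with confidence at least
    ``confidence_min`` and all five landmarks extract; otherwise the result
    carries the (possibly empty) masks with ``detectable=False``.
    """
    masks = segment_structures(image, threshold_quantile)
    if not masks.is_complete or min(masks.confidence.values()) < confidence_min:
        return DetectionResult(masks=masks, landmarks=None, detectable=False)
    try:
        landmarks = extract_keypoints(masks)
    except (MissingLandmarkError, ValidationError):
        return DetectionResult(masks=masks, landmarks=None, detectable=False)
    return DetectionResult(masks=masks, landmarks=landmarks, detectable=True)
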
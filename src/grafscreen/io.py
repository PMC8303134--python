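"""File formats: CVAT-dialect annotation XML, DICOM conversion, CSV dialects.

Annotations use the CVAT "images 1.1" XML dialect: one ``<image>`` element
per image carrying ``<polygon>`` elements for the three structure regions
and ``<points>`` elements for the five landmarks, coordinates as 0-based
sub-pixel "x,y" pairs.  Paired readings travel as long-format CSV with one
row per (image, rater).  DICOM inputs are converted to 8-bit grayscale PNG
with an anonymizing metadata sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pydicom
import yaml
from lxml import etree
from PIL import Image

from .errors import AnnotationParseError, DicomConversionError, ValidationError
from .gating import PairedReading, RaterReading
from .geometry import GrafMeasurement, LandmarkSet, Point2D, classify_graf

__all__ = [
    "POLYGON_LABELS",
    "POINT_LABELS",
    "ImageAnnotation",
    "AnnotationDocument",
    "write_annotations",
    "read_annotations",
    "truth_to_annotation",
    "convert_dicom",
    "write_paired_readings",
    "read_paired_readings",
    "write_measurements",
    "RunConfig",
    "load_config",
]

POLYGON_LABELS = ("ilium", "acetabulum", "labrum")
POINT_LABELS = ("check_upper", "triradiate", "lower_ilium", "bone_edge", "labrum_end")


@dataclass
class ImageAnnotation:
    """Annotations of one image: labeled structure polygons and landmark points."""

    name: str
    width: int
    height: int
    polygons: Dict[str, List[Tuple[float, float]]] = field(default_factory=dict)
    points: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label in self.polygons:
            if label not in POLYGON_LABELS:
                raise AnnotationParseError(f"unknown polygon label: {label!r}")
        for label, (x, y) in self.points.items():
            if label not in POINT_LABELS:
                raise AnnotationParseError(f"unknown point label: {label!r}")
            if not (0 <= x <= self.width - 1 and 0 <= y <= self.height - 1):
                raise ValidationError(
                    f"point {label} at ({x}, {y}) outside image bounds of {self.name}"
                )

    def landmark_set(self) -> LandmarkSet:
        missing = [l for l in POINT_LABELS if l not in self.points]
        if missing:
            raise AnnotationParseError(f"missing landmark points: {missing}")
        return LandmarkSet(**{l: Point2D(*self.points[l]) for l in POINT_LABELS})


@dataclass
class AnnotationDocument:
    images: List[ImageAnnotation] = field(default_factory=list)


def _fmt_points(pts: Sequence[Tuple[float, float]]) -> str:
    return ";".join(f"{x:.3f},{y:.3f}" for x, y in pts)


def _parse_points(s: str) -> List[Tuple[float, float]]:
    out = []
    for pair in s.split(";"):
        x, y = pair.split(",")
        out.append((float(x), float(y)))
    return out


def write_annotations(doc: AnnotationDocument, path) -> None:
    """Write a document in the CVAT images-1.1 dialect."""
    root = etree.Element("annotations")
    etree.SubElement(root, "version").text = "1.1"
    for i, img in enumerate(doc.images):
        el = etree.SubElement(
            root, "image", id=str(i), name=img.name,
            width=str(img.width), height=str(img.height),
        )
        for label in POLYGON_LABELS:
            if label in img.polygons:
                etree.SubElement(
                    el, "polygon", label=label, occluded="0",
                    points=_fmt_points(img.polygons[label]),
                )
        for label in POINT_LABELS:
            if label in img.points:
                etree.SubElement(
                    el, "points", label=label, occluded="0",
                    points=_fmt_points([img.points[label]]),
                )
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="utf-8")


def read_annotations(path) -> AnnotationDocument:
    """Parse a CVAT images-1.1 document; unknown labels raise, naming the label."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    if root.tag != "annotations":
        raise AnnotationParseError(f"expected <annotations> root, got <{root.tag}>")
    doc = AnnotationDocument()
    for el in root.findall("image"):
        img = ImageAnnotation(
            name=el.get("name"),
            width=int(el.get("width")),
            height=int(el.get("height")),
        )
        for poly in el.findall("polygon"):
            label = poly.get("label")
            if label not in POLYGON_LABELS:
                raise AnnotationParseError(f"unknown polygon label: {label!r}")
            img.polygons[label] = _parse_points(poly.get("points"))
        for pts in el.findall("points"):
            label = pts.get("label")
            if label not in POINT_LABELS:
                raise AnnotationParseError(f"unknown point label: {label!r}")
            parsed = _parse_points(pts.get("points"))
            img.points[label] = parsed[0]
        img.__post_init__()  # re-validate after population
        doc.images.append(img)
    return doc


def truth_to_annotation(truth, name: str) -> ImageAnnotation:
    """Encode a phantom's ground truth as one annotated image.

    Structure masks become their outer contours (sub-sampled to keep the
    polygons compact); landmarks become labeled points.
    """
    from skimage import measure as skmeasure

    h, w = next(iter(truth.masks.values())).shape
    img = ImageAnnotation(name=name, width=w, height=h)
    for label in POLYGON_LABELS:
        contours = skmeasure.find_contours(truth.masks[label].astype(float), 0.5)
        contour = max(contours, key=len)
        step = max(1, len(contour) // 40)
        img.polygons[label] = [(float(c), float(r)) for r, c in contour[::step]]
    for label, p in truth.landmarks.points().items():
        img.points[label] = (p.x, p.y)
    img.__post_init__()
    return img


# ---------------------------------------------------------------------------
# DICOM conversion

#: Conservative set of patient-identifying attributes never copied to the
#: sidecar (keyword form).
PHI_KEYWORDS = frozenset({
    "PatientName", "PatientID", "PatientBirthDate", "PatientSex",
    "PatientAge", "PatientAddress", "PatientTelephoneNumbers",
    "OtherPatientIDs", "OtherPatientNames", "IssuerOfPatientID",
    "ReferringPhysicianName", "PerformingPhysicianName", "OperatorsName",
    "InstitutionName", "InstitutionAddress", "StationName",
    "AccessionNumber", "StudyID", "DeviceSerialNumber",
})

_SIDECAR_KEYWORDS = (
    "Modality", "Rows", "Columns", "BitsAllocated", "BitsStored",
    "PhotometricInterpretation", "PixelSpacing", "TransducerData",
    "SOPClassUID",
)


def convert_dicom(dicom_path, png_path, sidecar_path=None) -> np.ndarray:
    """Convert a DICOM file to an 8-bit grayscale PNG plus anonymized sidecar.

    Pixel data are window-leveled onto 256 gray levels using the file's
    WindowCenter/WindowWidth when present, else the full data range.  The
    JSON sidecar carries only technical tags; every patient-identifying
    attribute is dropped.  Returns the 8-bit array.  Deterministic.
    """
    ds = pydicom.dcmread(str(dicom_path))
    if "PixelData" not in ds:
        raise DicomConversionError(f"{dicom_path}: no pixel data")
    arr = ds.pixel_array.astype(float)
    if arr.ndim != 2:
        raise DicomConversionError(f"{dicom_path}: expected a single-frame grayscale image")
    center = ds.get("WindowCenter", None)
    width = ds.get("WindowWidth", None)
    if center is not None and width is not None:
        center = float(center[0] if isinstance(center, pydicom.multival.MultiValue) else center)
        width = float(width[0] if isinstance(width, pydicom.multival.MultiValue) else width)
        lo, hi = center - width / 2.0, center + width / 2.0
    elif "BitsStored" in ds:
        # No window: map the nominal stored range onto the 256 gray levels,
        # so 8-bit data pass through unchanged.
        lo, hi = 0.0, float(2 ** int(ds.BitsStored) - 1)
    else:
        lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        hi = lo + 1.0
    out = np.clip((arr - lo) / (hi - lo) * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(out, mode="L").save(str(png_path))
    if sidecar_path is not None:
        meta = {}
        for kw in _SIDECAR_KEYWORDS:
            if kw in PHI_KEYWORDS:
                continue
            val = ds.get(kw, None)
            if val is not None:
                meta[kw] = str(val)
        Path(sidecar_path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out


# ---------------------------------------------------------------------------
# CSV dialects

_READING_COLUMNS = ["image_id", "rater", "detectable", "check_deg", "alpha_deg", "beta_deg"]


def write_paired_readings(readings: Sequence[PairedReading], path) -> None:
    """Long-format CSV: one row per (image, rater); angles blank when
    undetectable; angles written to 3 decimals."""
    rows = []
    for pr in readings:
        for rater, rd in (("ai", pr.ai), ("human", pr.human)):
            row = {"image_id": pr.image_id, "rater": rater, "detectable": int(rd.detectable)}
            if rd.detectable:
                m = rd.measurement
                row.update(
                    check_deg=round(m.check_deg, 3),
                    alpha_deg=round(m.alpha_deg, 3),
                    beta_deg=round(m.beta_deg, 3),
                )
            rows.append(row)
    pd.DataFrame(rows, columns=_READING_COLUMNS).to_csv(path, index=False)


def read_paired_readings(path) -> List[PairedReading]:
    df = pd.read_csv(path)
    missing = set(_READING_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"paired-readings CSV missing columns: {sorted(missing)}")
    out = []
    for image_id, grp in df.groupby("image_id", sort=False):
        raters = {}
        for _, row in grp.iterrows():
            if bool(row["detectable"]):
                alpha = float(row["alpha_deg"])
                raters[row["rater"]] = RaterReading(
                    detectable=True,
                    measurement=GrafMeasurement(
                        check_deg=float(row["check_deg"]),
                        alpha_deg=alpha,
                        beta_deg=float(row["beta_deg"]),
                        graf_call=classify_graf(alpha),
                    ),
                )
            else:
                raters[row["rater"]] = RaterReading(detectable=False, measurement=None)
        if set(raters) != {"ai", "human"}:
            raise ValidationError(f"image {image_id}: need exactly one ai and one human row")
        out.append(PairedReading(image_id=str(image_id), ai=raters["ai"], human=raters["human"]))
    return out


def write_measurements(measurements: Dict[str, Dict[str, GrafMeasurement]], path) -> None:
    """Measurement export: image_id, rater, check/alpha/beta (3 decimals),
    graf_call."""
    rows = []
    for image_id, by_rater in measurements.items():
        for rater, m in by_rater.items():
            rows.append({
                "image_id": image_id,
                "rater": rater,
                "check_deg": round(m.check_deg, 3),
                "alpha_deg": round(m.alpha_deg, 3),
                "beta_deg": round(m.beta_deg, 3),
                "graf_call": m.graf_call,
            })
    pd.DataFrame(
        rows,
        columns=["image_id", "rater", "check_deg", "alpha_deg", "beta_deg", "graf_call"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-wide knobs; defaults match the screening protocol."""

    detector: str = "classical"           # "classical" | "neural"
    threshold_quantile: float = 0.85
    check_tolerance: float = 5.0
    alpha_cutoff: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.detector not in ("classical", "neural"):
            raise ValidationError(f"unknown detector: {self.detector!r}")
        if not (0.0 < self.threshold_quantile < 1.0):
            raise ValidationError("threshold_quantile must lie in (0, 1)")
        if self.check_tolerance < 0 or not (0 <= self.alpha_cutoff <= 90):
            raise ValidationError("invalid tolerance or alpha cutoff")


def load_config(path=None, **overrides) -> RunConfig:
    """RunConfig from an optional YAML file plus keyword overrides."""
    values = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValidationError("config file must contain a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
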
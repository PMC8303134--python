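"""Synthetic Graf-plane hip ultrasound phantoms with exact ground truth.

The clinical image set behind this pipeline is private, so every downstream
stage is exercised on phantoms: minimal geometric scenes that contain the
three echogenic structures a Graf-plane image must show —

* the **ilium**: a thick bright near-vertical band whose tilt from the image
  vertical is the check angle,
* the **acetabular roof**: a bright wedge leaving the lower edge of the
  ilium along the bony roof line (its direction sets the alpha angle), and
* the **labrum**: a bright ellipse whose distal tip ends the cartilage roof
  line (its direction from the bone edge sets the beta angle),

over a darker soft-tissue background, degraded by multiplicative log-normal
speckle plus additive Gaussian noise and a global brightness factor.  The
construction is the inverse of the angle geometry: landmarks are laid out
so that recomputing check/alpha/beta from them reproduces the requested
angles to machine precision, which makes the generator a round-trip oracle
for the geometry and detection modules.

This is a first-order phantom, not a wave-propagation simulation: there is
no probe geometry, attenuation, shadowing or anisotropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .geometry import LandmarkSet, Point2D, classify_graf
from .gating import PairedReading, RaterReading
from .geometry import GrafMeasurement

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "AngleDistributions",
    "CohortItem",
    "generate_landmarks",
    "build_truth",
    "rasterize_phantom",
    "generate_cohort",
    "DEFAULT_RATER_SD",
]

#: Per-rater angle measurement noise SD (degrees).  Two independent raters
#: with this SD give an AI-human difference SD of ~4.5 deg, the inter-observer
#: variability the study population shows for the alpha angle.
DEFAULT_RATER_SD = 4.5 / math.sqrt(2.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic image; all angles in degrees.

    ``check_deg`` is signed (positive = distal iliac wing rotated toward +x).
    ``brightness_factor`` scales the whole scene, emulating the 75-100%
    brightness variation seen across acquisitions.
    """

    alpha_deg: float = 64.1
    beta_deg: float = 40.7
    check_deg: float = 0.0
    width_px: int = 256
    height_px: int = 256
    bone_intensity: float = 200.0
    soft_intensity: float = 60.0
    speckle_sigma: float = 0.25
    brightness_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_deg < 90.0):
            raise ValidationError(f"alpha_deg must lie in (0, 90), got {self.alpha_deg}")
        if not (0.0 < self.beta_deg < 90.0):
            raise ValidationError(f"beta_deg must lie in (0, 90), got {self.beta_deg}")
        if not abs(self.check_deg) <= 30.0:
            raise ValidationError(f"|check_deg| must be <= 30, got {self.check_deg}")
        if self.width_px < 64 or self.height_px < 64:
            raise ValidationError("width_px and height_px must be >= 64")
        if not (0.75 <= self.brightness_factor <= 1.0):
            raise ValidationError(
                f"brightness_factor must lie in [0.75, 1.00], got {self.brightness_factor}"
            )
        if not (0.0 <= self.bone_intensity <= 255.0 and 0.0 <= self.soft_intensity <= 255.0):
            raise ValidationError("intensities must lie in [0, 255]")
        if self.speckle_sigma < 0.0:
            raise ValidationError("speckle_sigma must be >= 0")


@dataclass(frozen=True)
class PhantomTruth:
    """Exact ground truth of one phantom: landmarks, per-structure masks, spec.

    After spatial augmentation the ``spec`` still records the *generation*
    parameters; the authoritative post-transform angles are the ones
    recomputed from ``landmarks``.
    """

    landmarks: LandmarkSet
    masks: dict[str, np.ndarray]  # keys: ilium, acetabulum, labrum (bool arrays)
    spec: PhantomSpec

    def __post_init__(self) -> None:
        keys = set(self.masks)
        if keys != {"ilium", "acetabulum", "labrum"}:
            raise ValidationError(f"masks must cover ilium/acetabulum/labrum, got {sorted(keys)}")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise ValidationError("masks must share image dimensions")
        for name, m in self.masks.items():
            if not m.any():
                raise ValidationError(f"{name} mask has no foreground pixels")
        names = list(self.masks)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if np.array_equal(self.masks[a], self.masks[b]):
                    raise ValidationError(f"masks {a} and {b} are identical")
        h, w = next(iter(self.masks.values())).shape
        for name, p in self.landmarks.points().items():
            if not (0.0 <= p.x <= w - 1 and 0.0 <= p.y <= h - 1):
                raise ValidationError(f"landmark {name} lies outside image bounds: ({p.x}, {p.y})")


def _frame(spec: PhantomSpec):
    """Unit vectors of the phantom scene for a given spec.

    u: along the baseline, pointing distally (downward for check=0);
    n: lateral unit vector (perpendicular to u, toward +x);
    w: along the bony roof line, making the alpha angle with the baseline;
    z: along the cartilage roof line, making the beta angle with the baseline.
    Both w and z point up-lateral (rotated from -u toward n).
    """
    c = math.radians(spec.check_deg)
    a = math.radians(spec.alpha_deg)
    b = math.radians(spec.beta_deg)
    u = np.array([math.sin(c), math.cos(c)])
    n = np.array([math.cos(c), -math.sin(c)])
    w = math.cos(a) * (-u) + math.sin(a) * n
    z = math.cos(b) * (-u) + math.sin(b) * n
    return u, n, w, z


def _layout(spec: PhantomSpec):
    """Scene measurements (pixels) and anchor points for a spec."""
    W, H = float(spec.width_px), float(spec.height_px)
    u, n, w, z = _frame(spec)
    t_band = max(3.0, 0.018 * W)  # ilium band half-width
    t_roof = max(2.5, 0.012 * W)  # roof wedge half-width
    ell_a = 0.08 * W  # labrum semi-major axis
    ell_b = max(2.0, 0.02 * W)  # labrum semi-minor axis
    gap = 3.0  # echo-dropout separation between structures
    check_upper = np.array([0.30 * W, 0.15 * H])
    baseline_len = 0.50 * H
    triradiate = check_upper + baseline_len * u
    lower_ilium = check_upper + 0.90 * baseline_len * u + (t_band + t_roof + gap) * n
    roof_len = 0.25 * W
    bone_edge = lower_ilium + roof_len * w
    labrum_near = bone_edge + (t_roof + gap) * z
    labrum_end = labrum_near + 2.0 * ell_a * z
    return {
        "u": u,
        "n": n,
        "w": w,
        "z": z,
        "t_band": t_band,
        "t_roof": t_roof,
        "ell_a": ell_a,
        "ell_b": ell_b,
        "check_upper": check_upper,
        "triradiate": triradiate,
        "baseline_len": baseline_len,
        "lower_ilium": lower_ilium,
        "bone_edge": bone_edge,
        "roof_len": roof_len,
        "labrum_near": labrum_near,
        "labrum_end": labrum_end,
    }


def generate_landmarks(spec: PhantomSpec) -> LandmarkSet:
    """Lay out the five landmarks so the geometry round-trips the spec angles.

    Deterministic given ``spec`` (the seed only drives noise, not geometry).
    The bony roof line leaves the lower-ilium point parallel to the roof
    direction, so offsetting that point laterally off the baseline (to keep
    the rasterized structures separable) does not perturb alpha.
    """
    lay = _layout(spec)

    def pt(v: np.ndarray) -> Point2D:
        return Point2D(float(v[0]), float(v[1]))

    return LandmarkSet(
        check_upper=pt(lay["check_upper"]),
        triradiate=pt(lay["triradiate"]),
        lower_ilium=pt(lay["lower_ilium"]),
        bone_edge=pt(lay["bone_edge"]),
        labrum_end=pt(lay["labrum_end"]),
    )


def _thick_segment_mask(shape, p0, direction, length, halfwidth) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - p0[0]
    dy = yy - p0[1]
    proj = dx * direction[0] + dy * direction[1]
    lat = dx * direction[1] - dy * direction[0]
    return (proj >= 0) & (proj <= length) & (np.abs(lat) <= halfwidth)


def _ellipse_mask(shape, center, axis_dir, a, b) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - center[0]
    dy = yy - center[1]
    proj = dx * axis_dir[0] + dy * axis_dir[1]
    lat = dx * axis_dir[1] - dy * axis_dir[0]
    return (proj / a) ** 2 + (lat / b) ** 2 <= 1.0


def build_truth(spec: PhantomSpec) -> PhantomTruth:
    """Landmarks plus exact binary masks for the three structures."""
    lay = _layout(spec)
    shape = (spec.height_px, spec.width_px)
    ilium = _thick_segment_mask(
        shape, lay["check_upper"], lay["u"], lay["baseline_len"], lay["t_band"]
    )
    acetabulum = _thick_segment_mask(
        shape, lay["lower_ilium"], lay["w"], lay["roof_len"], lay["t_roof"]
    )
    labrum_center = lay["labrum_near"] + lay["ell_a"] * lay["z"]
    labrum = _ellipse_mask(shape, labrum_center, lay["z"], lay["ell_a"], lay["ell_b"])
    return PhantomTruth(
        landmarks=generate_landmarks(spec),
        masks={"ilium": ilium, "acetabulum": acetabulum, "labrum": labrum},
        spec=spec,
    )


def rasterize_phantom(truth: PhantomTruth) -> np.ndarray:
    """Render an 8-bit grayscale image of one phantom.

    Structure pixels take ``bone_intensity``, background ``soft_intensity``;
    the whole scene is scaled by ``brightness_factor``, multiplied by
    mean-one log-normal speckle of scale ``speckle_sigma`` and perturbed by
    additive Gaussian noise (SD = 4 * speckle_sigma gray levels).  Seeded:
    the same spec renders a bit-identical image.
    """
    spec = truth.spec
    img = np.full((spec.height_px, spec.width_px), spec.soft_intensity, dtype=float)
    for m in truth.masks.values():
        img[m] = spec.bone_intensity
    img *= spec.brightness_factor
    if spec.speckle_sigma > 0.0:
        rng = np.random.default_rng(spec.seed)
        s = spec.speckle_sigma
        speckle = np.exp(rng.normal(-0.5 * s * s, s, size=img.shape))
        img = img * speckle + rng.normal(0.0, 4.0 * s, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class AngleDistributions:
    """Per-angle truncated-normal population parameters for cohort sampling.

    Defaults follow the study population summary (human readings):
    alpha 64.117 +/- 7.12 deg, beta 40.679 +/- 8.71 deg, with a centred
    check-angle tilt spread across acquisitions.
    """

    alpha_mean: float = 64.117
    alpha_sd: float = 7.12
    beta_mean: float = 40.679
    beta_sd: float = 8.71
    check_mean: float = 0.0
    check_sd: float = 4.0


@dataclass(frozen=True)
class CohortItem:
    """One simulated screening image with its truth and two simulated raters."""

    image: np.ndarray
    truth: PhantomTruth
    paired: PairedReading


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal; exact mean/SD only when the
    truncation is mild, which holds for the defaults."""
    out = rng.normal(mean, sd, size)
    bad = (out <= lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out <= lo) | (out >= hi)
    return out


def _reading(detectable: bool, check, alpha, beta) -> RaterReading:
    if not detectable:
        return RaterReading(detectable=False, measurement=None)
    alpha = float(np.clip(alpha, 0.0, 90.0))
    beta = float(np.clip(beta, 0.0, 90.0))
    return RaterReading(
        detectable=True,
        measurement=GrafMeasurement(
            check_deg=float(check),
            alpha_deg=alpha,
            beta_deg=beta,
            graf_call=classify_graf(alpha),
        ),
    )


def generate_cohort(
    n: int,
    angle_distributions: AngleDistributions | None = None,
    detect_failure_rate: float = 0.0,
    rater_sd: float = DEFAULT_RATER_SD,
    seed: int = 0,
    image_size: int = 256,
    speckle_sigma: float = 0.25,
    render: bool = True,
) -> list[CohortItem]:
    """Simulate a paired-reading screening cohort of ``n`` phantoms.

    Each phantom's true angles are drawn from ``angle_distributions``; the
    AI and human readings are the truth plus independent per-rater Gaussian
    noise of SD ``rater_sd`` (degrees) on every angle, and each rater
    independently fails to detect a ``detect_failure_rate`` fraction of
    images.  ``render=False`` skips rasterization when only the readings are
    needed.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValidationError(f"cohort size must be >= 1, got {n}")
    if not (0.0 <= detect_failure_rate < 1.0):
        raise ValidationError(
            f"detect_failure_rate must lie in [0, 1), got {detect_failure_rate}"
        )
    if rater_sd < 0.0:
        raise ValidationError("rater_sd must be >= 0")
    dist = angle_distributions or AngleDistributions()
    rng = np.random.default_rng(seed)
    alphas = _truncated_normal(rng, dist.alpha_mean, dist.alpha_sd, 25.0, 89.0, n)
    betas = _truncated_normal(rng, dist.beta_mean, dist.beta_sd, 10.0, 89.0, n)
    checks = _truncated_normal(rng, dist.check_mean, dist.check_sd, -29.0, 29.0, n)
    ai_noise = rng.normal(0.0, rater_sd, (n, 3)) if rater_sd > 0 else np.zeros((n, 3))
    hu_noise = rng.normal(0.0, rater_sd, (n, 3)) if rater_sd > 0 else np.zeros((n, 3))
    ai_fail = rng.random(n) < detect_failure_rate
    hu_fail = rng.random(n) < detect_failure_rate
    brightness = rng.uniform(0.75, 1.0, n)

    items: list[CohortItem] = []
    for i in range(n):
        spec = PhantomSpec(
            alpha_deg=float(alphas[i]),
            beta_deg=float(betas[i]),
            check_deg=float(checks[i]),
            width_px=image_size,
            height_px=image_size,
            speckle_sigma=speckle_sigma,
            brightness_factor=float(brightness[i]),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        truth = build_truth(spec)
        image = rasterize_phantom(truth) if render else np.zeros((0, 0), dtype=np.uint8)
        paired = PairedReading(
            image_id=f"phantom_{i:05d}",
            ai=_reading(
                not ai_fail[i],
                spec.check_deg + ai_noise[i, 0],
                spec.alpha_deg + ai_noise[i, 1],
                spec.beta_deg + ai_noise[i, 2],
            ),
            human=_reading(
                not hu_fail[i],
                spec.check_deg + hu_noise[i, 0],
                spec.alpha_deg + hu_noise[i, 1],
                spec.beta_deg + hu_noise[i, 2],
            ),
        )
        items.append(CohortItem(image=image, truth=truth, paired=paired))
    return items
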
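"""Phantom generator: round trips, determinism, noise model, cohorts."""

import numpy as np
import pytest

from grafscreen.errors import ValidationError
from grafscreen.geometry import compute_alpha, compute_beta, compute_check_angle
from grafscreen.phantom import (
    DEFAULT_RATER_SD,
    PhantomSpec,
    build_truth,
    generate_cohort,
    generate_landmarks,
    rasterize_phantom,
)


def test_landmark_round_trip_identity():
    ls = generate_landmarks(PhantomSpec(alpha_deg=60, beta_deg=55, check_deg=0, seed=1))
    assert compute_check_angle(ls) == pytest.approx(0.0, abs=1e-6)
    assert compute_alpha(ls) == pytest.approx(60.0, abs=1e-6)
    assert compute_beta(ls) == pytest.approx(55.0, abs=1e-6)


def test_landmarks_deterministic():
    spec = PhantomSpec(alpha_deg=60, beta_deg=55, check_deg=0, seed=1)
    assert generate_landmarks(spec) == generate_landmarks(spec)


def test_round_trip_arbitrary_angles():
    ls = generate_landmarks(PhantomSpec(alpha_deg=43.7, beta_deg=77.2, check_deg=-4.0, seed=9))
    assert compute_check_angle(ls) == pytest.approx(-4.0, abs=1e-6)
    assert compute_alpha(ls) == pytest.approx(43.7, abs=1e-6)
    assert compute_beta(ls) == pytest.approx(77.2, abs=1e-6)


def test_round_trip_100_random_valid_specs():
    rng = np.random.default_rng(12)
    for i in range(100):
        spec = PhantomSpec(
            alpha_deg=float(rng.uniform(1, 89)),
            beta_deg=float(rng.uniform(1, 89)),
            check_deg=float(rng.uniform(-30, 30)),
            seed=i,
        )
        ls = generate_landmarks(spec)
        assert compute_check_angle(ls) == pytest.approx(spec.check_deg, abs=1e-6)
        assert compute_alpha(ls) == pytest.approx(spec.alpha_deg, abs=1e-6)
        assert compute_beta(ls) == pytest.approx(spec.beta_deg, abs=1e-6)


def test_alpha_monotonicity():
    alphas = np.linspace(30, 85, 12)
    recomputed = [
        compute_alpha(generate_landmarks(PhantomSpec(alpha_deg=float(a), seed=0)))
        for a in alphas
    ]
    assert np.all(np.diff(recomputed) > 0)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"alpha_deg": 0.0},
        {"alpha_deg": 95.0},
        {"beta_deg": -3.0},
        {"check_deg": 31.0},
        {"width_px": 32},
        {"brightness_factor": 0.5},
        {"speckle_sigma": -0.1},
    ],
)
def test_spec_validation_names_bound(kwargs):
    with pytest.raises(ValidationError):
        PhantomSpec(**kwargs)


def test_truth_masks_disjoint_nonempty_in_bounds():
    truth = build_truth(PhantomSpec(seed=3))
    h, w = truth.masks["ilium"].shape
    for name, m in truth.masks.items():
        assert m.any(), name
    # structures must be separable for the detector: pairwise disjoint here
    assert not (truth.masks["ilium"] & truth.masks["acetabulum"]).any()
    assert not (truth.masks["acetabulum"] & truth.masks["labrum"]).any()
    for p in truth.landmarks.points().values():
        assert 0 <= p.x <= w - 1 and 0 <= p.y <= h - 1


def test_rasterize_zero_noise_exact_intensities(clean_truth, clean_image):
    spec = clean_truth.spec
    assert clean_image.dtype == np.uint8
    assert np.all(clean_image[clean_truth.masks["ilium"]] == spec.bone_intensity)
    union = (
        clean_truth.masks["ilium"]
        | clean_truth.masks["acetabulum"]
        | clean_truth.masks["labrum"]
    )
    assert np.all(clean_image[~union] == spec.soft_intensity)


def test_rasterize_seeded_determinism():
    spec = PhantomSpec(speckle_sigma=0.4, seed=11)
    img1 = rasterize_phantom(build_truth(spec))
    img2 = rasterize_phantom(build_truth(spec))
    assert np.array_equal(img1, img2)


def test_rasterize_bone_brighter_than_background():
    truth = build_truth(PhantomSpec(speckle_sigma=0.25, brightness_factor=0.8, seed=5))
    img = rasterize_phantom(truth).astype(float)
    union = truth.masks["ilium"] | truth.masks["acetabulum"] | truth.masks["labrum"]
    assert img[truth.masks["ilium"]].mean() > img[~union].mean()


def test_cohort_size_and_all_detectable_when_rate_zero():
    items = generate_cohort(10, detect_failure_rate=0.0, seed=2, render=False)
    assert len(items) == 10
    assert all(i.paired.ai.detectable and i.paired.human.detectable for i in items)


def test_cohort_zero_rater_noise_gives_identical_readings():
    items = generate_cohort(20, rater_sd=0.0, seed=2, render=False)
    for it in items:
        ai, hu = it.paired.ai.measurement, it.paired.human.measurement
        assert ai.alpha_deg == hu.alpha_deg
        assert ai.beta_deg == hu.beta_deg
        assert ai.check_deg == hu.check_deg


def test_cohort_paired_difference_sd_matches_sampling_distribution():
    """Independent per-rater noise of SD s gives a difference SD near s*sqrt(2);
    the default is calibrated so the difference SD is ~4.5 degrees."""
    items = generate_cohort(500, seed=21, render=False)
    diffs = [
        it.paired.ai.measurement.alpha_deg - it.paired.human.measurement.alpha_deg
        for it in items
    ]
    assert DEFAULT_RATER_SD * np.sqrt(2) == pytest.approx(4.5)
    assert 3.8 <= np.std(diffs, ddof=1) <= 5.2


def test_cohort_failure_rate_flags_undetectable():
    items = generate_cohort(400, detect_failure_rate=0.3, seed=8, render=False)
    ai_fail = np.mean([not i.paired.ai.detectable for i in items])
    hu_fail = np.mean([not i.paired.human.detectable for i in items])
    assert 0.2 < ai_fail < 0.4
    assert 0.2 < hu_fail < 0.4
    for it in items:
        if not it.paired.ai.detectable:
            assert it.paired.ai.measurement is None


def test_cohort_invalid_rate_rejected():
    with pytest.raises(ValidationError):
        generate_cohort(5, detect_failure_rate=1.0, render=False)
    with pytest.raises(ValidationError):
        generate_cohort(0, render=False)


def test_cohort_deterministic_given_seed():
    a = generate_cohort(5, seed=33)
    b = generate_cohort(5, seed=33)
    for x, y in zip(a, b):
        assert np.array_equal(x.image, y.image)
        assert x.paired == y.paired
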
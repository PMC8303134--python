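"""Angle geometry: primitives, sign conventions, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from grafscreen.errors import DegenerateLineError, ValidationError
from grafscreen.geometry import (
    LandmarkSet,
    Point2D,
    angle_between_lines,
    classify_graf,
    compute_alpha,
    compute_beta,
    compute_check_angle,
    measure,
)

P = Point2D


def _ls(check_upper, triradiate, lower_ilium, bone_edge, labrum_end):
    return LandmarkSet(
        check_upper=P(*check_upper),
        triradiate=P(*triradiate),
        lower_ilium=P(*lower_ilium),
        bone_edge=P(*bone_edge),
        labrum_end=P(*labrum_end),
    )


@pytest.mark.parametrize(
    "a1, a2, b1, b2, expected",
    [
        ((0, 0), (0, 10), (0, 0), (10, 0), 90.0),   # perpendicular
        ((0, 0), (5, 5), (2, 2), (9, 9), 0.0),       # same direction
        ((0, 0), (1, 1), (0, 0), (1, 0), 45.0),      # diagonal vs horizontal
    ],
)
def test_angle_between_lines_reference_cases(a1, a2, b1, b2, expected):
    assert angle_between_lines(P(*a1), P(*a2), P(*b1), P(*b2)) == pytest.approx(expected)


def test_angle_between_lines_symmetries():
    pts = P(1, 2), P(4, 7), P(-1, 3), P(2, 1)
    a = angle_between_lines(*pts)
    assert angle_between_lines(pts[1], pts[0], pts[2], pts[3]) == pytest.approx(a)
    assert angle_between_lines(pts[2], pts[3], pts[0], pts[1]) == pytest.approx(a)


def test_angle_between_lines_degenerate():
    with pytest.raises(DegenerateLineError):
        angle_between_lines(P(1, 1), P(1, 1), P(0, 0), P(1, 0))


coord = st.floats(min_value=-500, max_value=500, allow_nan=False, width=32)


@given(st.tuples(coord, coord), st.tuples(coord, coord), st.tuples(coord, coord), st.tuples(coord, coord))
def test_angle_matches_arccos_oracle(a1, a2, b1, b2):
    """Agreement with the explicit normalized-dot-product arc-cosine."""
    u = np.subtract(a2, a1)
    v = np.subtract(b2, b1)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-6 or nv < 1e-6:
        return
    expected = math.degrees(math.acos(min(1.0, abs(float(np.dot(u, v))) / (nu * nv))))
    got = angle_between_lines(P(*a1), P(*a2), P(*b1), P(*b2))
    assert got == pytest.approx(expected, abs=1e-9)
    assert 0.0 <= got <= 90.0


def test_check_angle_vertical_wing_is_zero():
    ls = _ls((100, 50), (100, 200), (110, 180), (150, 150), (180, 140))
    assert compute_check_angle(ls) == 0.0


def test_check_angle_known_tilt():
    ls = _ls((100, 50), (113.1, 200), (110, 180), (150, 150), (180, 140))
    assert compute_check_angle(ls) == pytest.approx(math.degrees(math.atan(13.1 / 150)), abs=0.01)
    assert compute_check_angle(ls) == pytest.approx(5.0, abs=0.01)


def test_check_angle_mirror_negates():
    ls = _ls((100, 50), (113.1, 200), (110, 180), (150, 150), (180, 140))
    mirrored = _ls((-100, 50), (-113.1, 200), (-110, 180), (-150, 150), (-180, 140))
    assert compute_check_angle(mirrored) == pytest.approx(-compute_check_angle(ls))


def test_alpha_constructed_30_60_90():
    # vertical baseline; roof line rises 50 over 86.6 laterally -> 60 deg
    ls = _ls((100, 50), (100, 200), (100, 200), (186.6, 150), (200, 140))
    assert compute_alpha(ls) == pytest.approx(60.0, abs=0.01)


def test_alpha_parallel_roof_is_zero():
    ls = _ls((100, 50), (100, 200), (120, 100), (120, 180), (150, 150))
    assert compute_alpha(ls) == pytest.approx(0.0)


def test_beta_known_configuration():
    # cartilage roof rises 34.04 over 50 laterally; measured from the
    # vertical baseline the angle is arctan(50/34.04)
    ls = _ls((100, 50), (100, 200), (100, 200), (60, 150), (110, 115.96))
    assert compute_beta(ls) == pytest.approx(math.degrees(math.atan(50 / 34.04)), abs=0.05)


def test_beta_parallel_roof_is_zero():
    ls = _ls((100, 50), (100, 200), (120, 100), (140, 150), (140, 100))
    assert compute_beta(ls) == pytest.approx(0.0)


@pytest.mark.parametrize(
    "alpha, call",
    [(64.117, "normal"), (59.9, "abnormal"), (60.0, "normal"), (0.0, "abnormal"), (90.0, "normal")],
)
def test_classify_graf(alpha, call):
    assert classify_graf(alpha) == call


def test_classify_graf_rejects_out_of_range():
    with pytest.raises(ValidationError):
        classify_graf(90.5)
    with pytest.raises(ValidationError):
        classify_graf(-1.0)


def _random_landmarks(rng):
    while True:
        pts = rng.uniform(-100, 100, size=(5, 2))
        try:
            return _ls(*map(tuple, pts))
        except ValidationError:  # pragma: no cover - coincident draw
            continue


def _transform(ls, A, t):
    pts = [(A @ np.array([p.x, p.y]) + t) for p in ls.points().values()]
    return _ls(*map(tuple, pts))


def test_rigid_rotation_shifts_check_preserves_alpha_beta():
    rng = np.random.default_rng(4)
    for _ in range(100):
        ls = _random_landmarks(rng)
        theta = float(rng.uniform(-20, 20))
        r = math.radians(theta)
        # y-down frame: this rotation adds theta to the check angle
        A = np.array([[math.cos(r), math.sin(r)], [-math.sin(r), math.cos(r)]])
        rotated = _transform(ls, A, np.zeros(2))
        assert compute_alpha(rotated) == pytest.approx(compute_alpha(ls), abs=1e-8)
        assert compute_beta(rotated) == pytest.approx(compute_beta(ls), abs=1e-8)
        c0, c1 = compute_check_angle(ls), compute_check_angle(rotated)
        shift = (c1 - c0 - theta) % 180.0
        assert min(shift, 180.0 - shift) == pytest.approx(0.0, abs=1e-8)


def test_translation_and_scaling_leave_angles_unchanged():
    rng = np.random.default_rng(5)
    for _ in range(100):
        ls = _random_landmarks(rng)
        s = float(rng.uniform(0.2, 5.0))
        t = rng.uniform(-50, 50, 2)
        moved = _transform(ls, s * np.eye(2), t)
        for fn in (compute_check_angle, compute_alpha, compute_beta):
            assert fn(moved) == pytest.approx(fn(ls), abs=1e-9)


def test_measure_bundles_all_angles():
    dx = 50 * math.tan(math.radians(65))  # bony roof clearly above the cutoff
    ls = _ls((100, 50), (100, 200), (100, 200), (100 + dx, 150), (200, 100))
    m = measure(ls)
    assert m.check_deg == pytest.approx(0.0)
    assert m.alpha_deg == pytest.approx(65.0, abs=0.01)
    assert m.graf_call == "normal"
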
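"""Agreement statistics: kappa/percent/positive agreement, ICC, paired summary."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from grafscreen.agreement import (
    cicchetti_band,
    cohens_kappa,
    icc_agreement,
    paired_summary,
    percent_agreement,
    positive_agreement,
)
from grafscreen.errors import ValidationError
from grafscreen.gating import ContingencyTable2x2

REFERENCE_TABLE = ContingencyTable2x2(320, 49, 49, 94)


@pytest.mark.parametrize(
    "table, expected",
    [
        (REFERENCE_TABLE, 80.9),
        (ContingencyTable2x2(10, 0, 0, 10), 100.0),
        (ContingencyTable2x2(0, 5, 5, 0), 0.0),
    ],
)
def test_percent_agreement(table, expected):
    assert percent_agreement(table) == pytest.approx(expected, abs=0.05)


@pytest.mark.parametrize(
    "table, expected, tol",
    [
        (REFERENCE_TABLE, 0.87, 0.005),
        (ContingencyTable2x2(10, 0, 0, 0), 1.0, 0),
        (ContingencyTable2x2(0, 3, 3, 10), 0.0, 0),
    ],
)
def test_positive_agreement(table, expected, tol):
    assert positive_agreement(table) == pytest.approx(expected, abs=tol)


def test_positive_agreement_undefined():
    with pytest.raises(ValidationError):
        positive_agreement(ContingencyTable2x2(0, 0, 0, 4))


@pytest.mark.parametrize(
    "table, expected, tol",
    [
        (REFERENCE_TABLE, 0.525, 0.0005),
        (ContingencyTable2x2(10, 0, 0, 10), 1.0, 1e-12),
        (ContingencyTable2x2(25, 25, 25, 25), 0.0, 1e-12),
    ],
)
def test_cohens_kappa_reference_values(table, expected, tol):
    assert cohens_kappa(table).value == pytest.approx(expected, abs=tol)


def test_kappa_invariant_under_label_swap():
    t = ContingencyTable2x2(37, 11, 5, 19)
    swapped = ContingencyTable2x2(19, 5, 11, 37)
    assert cohens_kappa(t).value == pytest.approx(cohens_kappa(swapped).value)


def test_kappa_and_percent_match_bruteforce_enumeration():
    """Over every 2x2 table with n <= 12, kappa matches an independent
    label-expansion computation and percent agreement matches counting."""
    for n in range(2, 13):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    x = np.array([1] * (a + b) + [0] * (c + d))
                    y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
                    t = ContingencyTable2x2(a, b, c, d)
                    assert percent_agreement(t) == pytest.approx(100.0 * np.mean(x == y))
                    if len(set(x)) < 2 or len(set(y)) < 2:
                        continue  # sklearn kappa undefined for constant raters
                    assert cohens_kappa(t).value == pytest.approx(
                        cohen_kappa_score(x, y), abs=1e-10
                    )


def test_kappa_ci_brackets_estimate():
    r = cohens_kappa(REFERENCE_TABLE)
    assert r.ci_low < r.value < r.ci_high
    assert -1 <= r.ci_low and r.ci_high <= 1


@pytest.mark.parametrize(
    "icc, band",
    [(0.764, "excellent"), (0.743, "good"), (0.39, "poor"), (0.40, "fair"),
     (0.59, "fair"), (0.60, "good"), (0.75, "excellent"), (1.0, "excellent")],
)
def test_cicchetti_bands(icc, band):
    assert cicchetti_band(icc) == band


def test_icc_perfect_agreement():
    pairs = [(50.0, 50.0), (60.0, 60.0), (70.0, 70.0), (65.0, 65.0)]
    r = icc_agreement(pairs)
    assert r.icc == pytest.approx(1.0)
    assert r.band == "excellent"


def test_icc_six_pair_frozen_oracle():
    """Expected value frozen from the explicit two-way ANOVA mean-squares
    decomposition (MSR/MSC/MSE) computed independently of the module."""
    pairs = [(50, 52), (60, 59), (70, 71), (80, 78), (55, 57), (65, 62)]
    assert icc_agreement(pairs).icc == pytest.approx(0.9816147082334132, abs=1e-9)


def test_icc_matches_pingouin():
    import pandas as pd
    import pingouin as pg

    rng = np.random.default_rng(42)
    subj = rng.normal(60, 7, 50)
    pairs = [(s + rng.normal(0, 3), s + rng.normal(0, 3)) for s in subj]
    mine = icc_agreement(pairs)
    df = pd.DataFrame({
        "subject": np.repeat(range(50), 2),
        "rater": ["ai", "human"] * 50,
        "score": np.array(pairs).ravel(),
    })
    ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    row = ref[ref.Type == "ICC(A,1)"].iloc[0] if "ICC(A,1)" in set(ref.Type) \
        else ref[ref.Type == "ICC2"].iloc[0]
    assert mine.icc == pytest.approx(float(row.ICC), abs=1e-9)
    lo, hi = row.CI95
    assert mine.ci_low == pytest.approx(float(lo), abs=0.01)
    assert mine.ci_high == pytest.approx(float(hi), abs=0.01)


def test_icc_absolute_agreement_penalizes_constant_offset():
    rng = np.random.default_rng(3)
    x = rng.normal(60, 7, 200)
    iccs = [icc_agreement(np.column_stack([x, x + c])).icc for c in (0.0, 2.0, 5.0, 10.0)]
    assert iccs[0] == pytest.approx(1.0)
    assert all(hi > lo for hi, lo in zip(iccs, iccs[1:]))


def test_icc_parameter_recovery():
    """Shared subject variance sigma_s^2 with rater noise sigma_e^2 recovers
    ICC ~ sigma_s^2/(sigma_s^2+sigma_e^2) within 0.05 at n=2000."""
    rng = np.random.default_rng(7)
    sig_s, sig_e = 7.0, 3.5
    target = sig_s**2 / (sig_s**2 + sig_e**2)
    s = rng.normal(60, sig_s, 2000)
    pairs = np.column_stack([s + rng.normal(0, sig_e, 2000), s + rng.normal(0, sig_e, 2000)])
    assert icc_agreement(pairs).icc == pytest.approx(target, abs=0.05)


def test_icc_rejects_degenerate_inputs():
    with pytest.raises(ValidationError):
        icc_agreement([(1.0, 1.0), (2.0, 2.0)])  # too few
    with pytest.raises(ValidationError):
        icc_agreement([(5.0, 5.0)] * 10)  # constant


def test_paired_summary_identical_pairs():
    s = paired_summary([(60.0, 60.0), (70.0, 70.0)])
    assert s.mad == 0.0 and s.diff_mean == 0.0
    assert s.within5_fraction == 1.0 and s.concordance60_fraction == 1.0


def test_paired_summary_hand_arithmetic():
    s = paired_summary([(1.0, 2.0), (3.0, 5.0)])
    assert s.mad == pytest.approx(1.5)
    assert s.diff_mean == pytest.approx(-1.5)


def test_paired_summary_within5_strict_and_concordance_boundary():
    s = paired_summary([(60.0, 65.0), (62.0, 60.0), (59.9, 60.0)])
    # |60-65| = 5 exactly -> NOT within 5 (strict); the other two qualify
    assert s.within5_fraction == pytest.approx(2 / 3)
    # 60.0 classifies normal (boundary inclusive); 59.9 abnormal
    assert s.concordance60_fraction == pytest.approx(2 / 3)


def test_paired_summary_diff_sd_from_simulated_cohort():
    from grafscreen.phantom import generate_cohort

    items = generate_cohort(320, seed=17, render=False)
    pairs = [
        (it.paired.ai.measurement.alpha_deg, it.paired.human.measurement.alpha_deg)
        for it in items
    ]
    s = paired_summary(pairs)
    assert 3.9 <= s.diff_sd <= 5.1


def test_paired_summary_empty_rejected():
    with pytest.raises(ValidationError):
        paired_summary([])
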
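"""Inter-rater agreement statistics for paired screening readings.

Categorical agreement on the check-angle gate uses a 2x2 contingency table:
percent agreement 100*(a+d)/n, positive percent agreement 2a/(2a+b+c), and
Cohen's kappa (p_o - p_e)/(1 - p_e) with the usual marginal-product chance
term.  Continuous agreement on the alpha/beta angles uses the two-way
random-effects, absolute-agreement, single-measurement intraclass
correlation ICC(A,1):

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with row (subject), column (rater) and error mean squares from the two-way
ANOVA decomposition, interpreted on the Cicchetti bands
(<0.40 poor, 0.40-0.59 fair, 0.60-0.74 good, >=0.75 excellent).  Confidence
intervals follow McGraw & Wong's F-based construction.  Paired-difference
summaries (MAD, mean +/- SD of AI-human, fraction within 5 degrees, and
concordance of the 60-degree normal/abnormal call) complete the report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ValidationError
from .gating import ContingencyTable2x2
from .geometry import classify_graf

__all__ = [
    "percent_agreement",
    "positive_agreement",
    "cohens_kappa",
    "KappaResult",
    "icc_agreement",
    "IccResult",
    "cicchetti_band",
    "paired_summary",
    "PairedSummary",
]


def percent_agreement(t: ContingencyTable2x2) -> float:
    """Raw agreement 100*(a+d)/n, in percent."""
    if t.n == 0:
        raise ValidationError("contingency table is empty")
    return 100.0 * (t.a + t.d) / t.n


def positive_agreement(t: ContingencyTable2x2) -> float:
    """Positive percent agreement 2a/(2a+b+c), as a fraction."""
    denom = 2 * t.a + t.b + t.c
    if denom == 0:
        raise ValidationError("positive agreement undefined: no positive calls")
    return 2.0 * t.a / denom


@dataclass(frozen=True)
class KappaResult:
    value: float
    ci_low: float
    ci_high: float


def cohens_kappa(t: ContingencyTable2x2, ci_level: float = 0.95) -> KappaResult:
    """Cohen's kappa on a 2x2 table with an asymptotic-SE confidence interval.

    SE uses the large-sample approximation sqrt(p_o(1-p_o)/n) / (1-p_e).
    """
    n = t.n
    if n < 2:
        raise ValidationError("kappa needs at least 2 observations")
    po = (t.a + t.d) / n
    pe = ((t.a + t.b) * (t.a + t.c) + (t.c + t.d) * (t.b + t.d)) / (n * n)
    if pe == 1.0:
        raise ValidationError("kappa undefined: expected agreement is 1")
    kappa = (po - pe) / (1.0 - pe)
    se = math.sqrt(max(po * (1.0 - po), 0.0) / n) / (1.0 - pe)
    zq = stats.norm.ppf(0.5 + ci_level / 2.0)
    return KappaResult(
        value=kappa,
        ci_low=max(-1.0, kappa - zq * se),
        ci_high=min(1.0, kappa + zq * se),
    )


def cicchetti_band(icc: float) -> str:
    """Cicchetti interpretation band for an ICC value."""
    if icc < 0.40:
        return "poor"
    if icc < 0.60:
        return "fair"
    if icc < 0.75:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    band: str


def _mean_squares(data: np.ndarray) -> Tuple[float, float, float]:
    """Row, column and error mean squares of a subjects x raters table."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_agreement(
    pairs: Sequence[Tuple[float, float]], ci_level: float = 0.95
) -> IccResult:
    """ICC(A,1) between two raters over paired continuous measurements.

    Two-way random effects, absolute agreement, single measurement — the
    form appropriate for two raters independently measuring the same images
    where systematic offsets between raters should count as disagreement.
    """
    data = np.asarray(pairs, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValidationError("pairs must be a sequence of (ai, human) values")
    n, k = data.shape
    if n < 3:
        raise ValidationError("ICC needs at least 3 pairs")
    if np.ptp(data) == 0.0:
        raise ValidationError("ICC undefined for constant measurements")
    msr, msc, mse = _mean_squares(data)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise ValidationError("ICC undefined: non-positive denominator")
    icc = (msr - mse) / denom

    # McGraw & Wong CI for ICC(A,1) via a Satterthwaite-df F interval.
    alpha = 1.0 - ci_level
    r = icc
    a_coef = (k * r) / (n * (1.0 - r)) if r < 1.0 else np.inf
    b_coef = 1.0 + (k * r * (n - 1.0)) / (n * (1.0 - r)) if r < 1.0 else np.inf
    if np.isfinite(a_coef) and (a_coef * msc + b_coef * mse) > 0:
        v = (a_coef * msc + b_coef * mse) ** 2 / (
            (a_coef * msc) ** 2 / (k - 1.0)
            + (b_coef * mse) ** 2 / ((n - 1.0) * (k - 1.0))
        )
        f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
        f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
        lower = (
            n * (msr - f_l * mse)
            / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
        upper = (
            n * (f_u * msr - mse)
            / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
        )
        lower, upper = float(min(lower, icc)), float(max(upper, icc))
    else:
        lower, upper = icc, icc
    return IccResult(
        icc=float(icc),
        ci_low=max(-1.0, lower),
        ci_high=min(1.0, upper),
        band=cicchetti_band(float(icc)),
    )


@dataclass(frozen=True)
class PairedSummary:
    """Paired AI-vs-human angle comparison summaries (degrees / fractions)."""

    mad: float
    diff_mean: float
    diff_sd: float
    within5_fraction: float
    concordance60_fraction: float
    n: int


def paired_summary(
    pairs: Sequence[Tuple[float, float]],
    discrepancy_deg: float = 5.0,
    cutoff_deg: float = 60.0,
) -> PairedSummary:
    """MAD, difference stats and threshold concordance for (ai, human) pairs.

    ``within5_fraction`` counts |ai - human| strictly below ``discrepancy_deg``;
    ``concordance60_fraction`` counts pairs where both readings fall on the
    same side of the cutoff, with the boundary itself classified normal.
    """
    data = np.asarray(pairs, dtype=float)
    if data.size == 0:
        raise ValidationError("paired summary needs at least 1 pair")
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValidationError("pairs must be a sequence of (ai, human) values")
    diff = data[:, 0] - data[:, 1]
    n = len(diff)
    calls_ai = [classify_graf(float(np.clip(v, 0, 90)), cutoff_deg) for v in data[:, 0]]
    calls_hu = [classify_graf(float(np.clip(v, 0, 90)), cutoff_deg) for v in data[:, 1]]
    concord = float(np.mean([x == y for x, y in zip(calls_ai, calls_hu)]))
    return PairedSummary(
        mad=float(np.mean(np.abs(diff))),
        diff_mean=float(np.mean(diff)),
        diff_sd=float(np.std(diff, ddof=1)) if n > 1 else 0.0,
        within5_fraction=float(np.mean(np.abs(diff) < discrepancy_deg)),
        concordance60_fraction=concord,
        n=n,
    )
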
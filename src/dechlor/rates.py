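"""Production-rate estimation from bottle time series.

Ethene and methane production rates are the slopes of ordinary
least-squares fits of per-bottle mass (μmol/bottle) against time (days)
over a stated window — typically a phase of roughly linear accumulation
between feedings. Treatments run in duplicate are summarized as
mean ± half-range, and treatments are compared with a two-sample t test
on pooled-regression slopes (Welch–Satterthwaite degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import MassSeries

__all__ = [
    "RateEstimate",
    "TreatmentRate",
    "production_rate",
    "treatment_rate",
    "compare_rates",
    "compare_rates_welch_bottles",
]


@dataclass(frozen=True)
class RateEstimate:
    """OLS slope of mass vs time for one bottle, compound and window."""

    bottle_id: str
    compound: str
    window: tuple[float, float]  # (day_start, day_end), inclusive
    slope: float  # μmol/bottle/day
    slope_se: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class TreatmentRate:
    """Duplicate-bottle summary: mean slope ± half-range."""

    compound: str
    window: tuple[float, float]
    mean: float
    half_range: float
    bottles: tuple[RateEstimate, ...]


def production_rate(
    series: MassSeries,
    window: tuple[float, float],
    censored_as_zero: bool = False,
) -> RateEstimate:
    """Fit a production rate (μmol/bottle/day) over ``window``.

    Censored (below-detection) points are excluded by default;
    ``censored_as_zero=True`` instead keeps them at 0, the plotting
    convention. At least 3 usable points are required.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"empty window {window}")
    days, values = [], []
    for day, value, censored in series.points:
        if not lo <= day <= hi:
            continue
        if censored and not censored_as_zero:
            continue
        days.append(day)
        values.append(value)
    if len(days) < 3:
        raise ValueError(
            f"{series.bottle_id}/{series.compound}: only {len(days)} usable "
            f"points in window {window}; need >= 3"
        )
    x = np.asarray(days)
    y = np.asarray(values)
    if np.ptp(x) == 0:
        raise ValueError(f"{series.bottle_id}: zero time span in window")
    fit = stats.linregress(x, y)
    return RateEstimate(
        bottle_id=series.bottle_id,
        compound=series.compound,
        window=window,
        slope=float(fit.slope),
        slope_se=float(fit.stderr),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=len(days),
    )


def treatment_rate(bottles: Sequence[RateEstimate]) -> TreatmentRate:
    """Summarize replicate bottles of one treatment as mean ± half-range."""
    if not bottles:
        raise ValueError("no bottles supplied")
    compounds = {b.compound for b in bottles}
    windows = {b.window for b in bottles}
    if len(compounds) > 1 or len(windows) > 1:
        raise ValueError(
            f"mixed compounds {compounds} or windows {windows} in one treatment"
        )
    slopes = [b.slope for b in bottles]
    return TreatmentRate(
        compound=bottles[0].compound,
        window=bottles[0].window,
        mean=float(np.mean(slopes)),
        half_range=(max(slopes) - min(slopes)) / 2.0,
        bottles=tuple(bottles),
    )


def pooled_rate(
    series: Sequence[MassSeries],
    window: tuple[float, float],
    censored_as_zero: bool = False,
) -> RateEstimate:
    """Single OLS fit pooling all replicate bottles of a treatment."""
    if not series:
        raise ValueError("no series supplied")
    lo, hi = window
    days, values = [], []
    for s in series:
        for day, value, censored in s.points:
            if not lo <= day <= hi:
                continue
            if censored and not censored_as_zero:
                continue
            days.append(day)
            values.append(value)
    if len(days) < 3:
        raise ValueError(f"only {len(days)} usable pooled points; need >= 3")
    fit = stats.linregress(np.asarray(days), np.asarray(values))
    return RateEstimate(
        bottle_id="+".join(sorted({s.bottle_id for s in series})),
        compound=series[0].compound,
        window=window,
        slope=float(fit.slope),
        slope_se=float(fit.stderr),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=len(days),
    )


def compare_rates(a: RateEstimate, b: RateEstimate) -> float:
    """Two-sided p-value for a difference between two regression slopes.

    t = (slope_a − slope_b) / sqrt(se_a² + se_b²), with Welch–Satterthwaite
    degrees of freedom built from the two regressions' residual degrees of
    freedom (n − 2 each). Intended for pooled-regression fits (one per
    treatment); see :func:`compare_rates_welch_bottles` for the per-bottle
    alternative.
    """
    for est in (a, b):
        if est.n_points < 3:
            raise ValueError("need >= 3 points per regression")
        if est.slope_se <= 0:
            raise ValueError(
                f"{est.bottle_id}: zero slope standard error; "
                "degenerate (noise-free) input"
            )
    diff = a.slope - b.slope
    se = np.hypot(a.slope_se, b.slope_se)
    t = diff / se
    va, vb = a.slope_se**2, b.slope_se**2
    df = (va + vb) ** 2 / (va**2 / (a.n_points - 2) + vb**2 / (b.n_points - 2))
    return float(2.0 * stats.t.sf(abs(t), df))


def compare_rates_welch_bottles(
    a: Sequence[RateEstimate], b: Sequence[RateEstimate]
) -> float:
    """Welch t test on per-bottle slopes (alternative comparison mode).

    Requires >= 2 bottles per treatment with non-identical slopes. With
    duplicate bottles this has a single degree of freedom per group and is
    very conservative; the pooled-slope test is the default for that reason.
    """
    sa = [e.slope for e in a]
    sb = [e.slope for e in b]
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("Welch per-bottle mode needs >= 2 bottles per treatment")
    if np.var(sa) == 0 and np.var(sb) == 0:
        raise ValueError("zero variance in both treatments; nothing to test")
    return float(stats.ttest_ind(sa, sb, equal_var=False).pvalue)
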
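"""The school-leaving-age natural experiment (ROSLA).

In September 1972 the UK minimum school-leaving age rose from 15 to 16; the
first school cohort affected was born in September 1957.  The design compares
the first affected 12-month school cohort with the last unaffected one and
subtracts the secular trend, estimated as the average year-on-year difference
in cohort means over the ten school-year cohorts on each side of the cutoff
(the pair straddling the cutoff is excluded).  Scaling the trend-adjusted
jump by the jump in the probability of staying past 15 turns the reform
effect into the effect of one additional school year.

Because the trend is an equal-weight average of consecutive differences it
telescopes: only four cohort means enter the estimator, and the whole thing
is a linear functional of individual outcomes, which gives exact delta-method
standard errors from within-cohort variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import DataError, DegenerateInstrumentError
from .iv import Z95, EffectEstimate, EstimationRequest

DEFAULT_CUTOFF = (1957, 9)  # first birth month affected by the 1972 reform


def assign_reform_exposure(
    birth_year, birth_month, cutoff: Tuple[int, int] = DEFAULT_CUTOFF
):
    """1 if born in or after the cutoff month (September 1957), else 0.

    Accepts scalars or array-likes; missing birth months yield NaN (the row is
    then excluded from reform analyses).
    """
    by = np.asarray(birth_year, dtype=float)
    bm = np.asarray(birth_month, dtype=float)
    cy, cm = cutoff
    months = 12 * (by - cy) + (bm - cm)
    out = np.where(np.isnan(months), np.nan, (months >= 0).astype(float))
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class ReformEstimate:
    """Trend-adjusted reform contrast for one outcome."""

    outcome: str
    delta: float  # jump at the cutoff after trend adjustment
    delta_se: float
    trend: float  # average year-on-year cohort difference
    trend_se: float
    first_stage: Optional[float] = None  # reform effect on P(stayed past 15)
    first_stage_se: Optional[float] = None
    per_year: Optional[float] = None  # delta scaled per additional school year
    per_year_se: Optional[float] = None
    n: int = 0
    notes: str = ""

    def ci(self, which: str = "per_year"):
        v, s = getattr(self, which), getattr(self, f"{which}_se")
        return (v - Z95 * s, v + Z95 * s)


def _month_index(d: pd.DataFrame, cutoff: Tuple[int, int]) -> np.ndarray:
    cy, cm = cutoff
    return (
        12 * (d["birth_year"].to_numpy(dtype=float) - cy)
        + d["birth_month"].to_numpy(dtype=float)
        - cm
    )


def _did_linear(
    d: pd.DataFrame,
    col: str,
    bandwidth_months: int,
    trend_window_years: int,
    cutoff: Tuple[int, int],
    weight_col: Optional[str],
):
    """Coefficient vector a and residuals r for the trend-adjusted jump.

    The estimator is delta = sum_i a_i y_i; its variance is sum a_i^2 r_i^2
    with r_i the residual from the (weighted) school-cohort mean.
    """
    K = trend_window_years
    mo = _month_index(d, cutoff)
    cohort = np.floor(mo / 12.0).astype(int)  # school-year cohorts, Sep-Aug
    y = d[col].to_numpy(dtype=float)
    w = d[weight_col].to_numpy(dtype=float) if weight_col else np.ones(len(d))
    ok = np.isfinite(mo) & np.isfinite(y) & np.isfinite(w)
    mo, cohort, y, w = mo[ok], cohort[ok], y[ok], w[ok]

    in_window = (cohort >= -K) & (cohort <= K - 1)
    for c in range(-K, K):
        if not np.any(cohort == c):
            raise DataError(f"empty school-year cohort {c} relative to the cutoff ({col})")

    # weighted cohort means and residuals inside the trend window
    means = {c: np.average(y[cohort == c], weights=w[cohort == c]) for c in range(-K, K)}
    resid = np.zeros_like(y)
    for c in range(-K, K):
        sel = cohort == c
        resid[sel] = y[sel] - means[c]

    def cell_weights(mask: np.ndarray) -> np.ndarray:
        tw = w[mask].sum()
        if not mask.any() or tw <= 0:
            raise DataError(f"empty cell in reform design for {col!r}")
        return w[mask] / tw

    # jump cells: first affected / last unaffected bandwidth around the cutoff
    jump_a = np.zeros_like(y)
    j1 = (mo >= 0) & (mo < bandwidth_months)
    j0 = (mo >= -bandwidth_months) & (mo < 0)
    jump_a[j1] += cell_weights(j1)
    jump_a[j0] -= cell_weights(j0)

    # trend: average of the 2K-2 year-on-year cohort differences excluding the
    # straddling pair (m0 - m(-1)); the average telescopes to four cohort means:
    # trend = [ (m(-1) - m(-K)) + (m(K-1) - m0) ] / (2K - 2)
    denom = 2 * K - 2
    trend_a = np.zeros_like(y)
    for c, coef in {-1: 1.0, -K: -1.0, K - 1: 1.0, 0: -1.0}.items():
        sel = cohort == c
        trend_a[sel] += (coef / denom) * cell_weights(sel)
    trend = float(trend_a @ y)
    trend_se = float(np.sqrt(np.sum((trend_a * resid) ** 2)))

    a = jump_a - trend_a  # delta = jump - trend
    delta = float(a @ y)
    se = float(np.sqrt(np.sum((a * resid) ** 2)))
    return a, resid, delta, se, trend, trend_se, int(in_window.sum()), ok


def did_reform_effect(
    cohort: pd.DataFrame,
    outcome: str,
    bandwidth_months: int = 12,
    trend_window_years: int = 10,
    cutoff: Tuple[int, int] = DEFAULT_CUTOFF,
    weight_col: Optional[str] = None,
) -> ReformEstimate:
    """Trend-adjusted jump in ``outcome`` at the reform cutoff.

    delta = (mean of the first affected 12-month cohort)
          - (mean of the last unaffected cohort)
          - (average year-on-year difference over the +/-10-year window,
             excluding the pair straddling the cutoff).

    Exactly removes any outcome that is affine in school cohort.
    """
    if outcome not in cohort.columns:
        raise DataError(f"outcome column {outcome!r} not found")
    _, _, delta, se, trend, trend_se, n, _ = _did_linear(
        cohort, outcome, bandwidth_months, trend_window_years, cutoff, weight_col
    )
    return ReformEstimate(
        outcome=outcome,
        delta=delta,
        delta_se=se,
        trend=trend,
        trend_se=trend_se,
        n=n,
    )


def reform_iv_per_year(
    cohort: pd.DataFrame,
    outcome: str,
    request: Optional[EstimationRequest] = None,
    exposure: str = "stayed_past_15",
    bandwidth_months: int = 12,
    trend_window_years: int = 10,
    cutoff: Tuple[int, int] = DEFAULT_CUTOFF,
    weight_col: Optional[str] = None,
    scale: str = "continuous",
) -> Tuple[ReformEstimate, EffectEstimate]:
    """Per-year-of-schooling effect: trend-adjusted jump ratio.

    per_year = delta(outcome) / delta(exposure), both numerator and
    denominator trend adjusted, with the delta-method standard error using
    the exact covariance of the two linear functionals (they share the same
    individuals).  A first stage with |t| < 2 attaches a weak-instrument
    warning rather than failing.
    """
    if request is not None:
        outcome = request.outcome
        weight_col = request.weight_col
        scale = request.scale
    d = cohort.dropna(subset=[outcome, exposure, "birth_year", "birth_month"]).copy()
    a_y, r_y, dy, se_y, trend, trend_se, n, _ = _did_linear(
        d, outcome, bandwidth_months, trend_window_years, cutoff, weight_col
    )
    a_x, r_x, dx, se_x, _, _, _, _ = _did_linear(
        d, exposure, bandwidth_months, trend_window_years, cutoff, weight_col
    )
    if dx == 0:
        raise DegenerateInstrumentError("reform first stage is exactly zero")
    cov = float(np.sum(a_y * r_y * a_x * r_x))
    psi = dy / dx
    var = se_y**2 / dx**2 + dy**2 * se_x**2 / dx**4 - 2 * dy * cov / dx**3
    psi_se = float(np.sqrt(max(var, 0.0)))
    notes = ""
    if se_x > 0 and abs(dx / se_x) < 2:
        notes = f"weak-instrument warning: first-stage |t| = {abs(dx / se_x):.2f} < 2"
    ref = ReformEstimate(
        outcome=outcome,
        delta=dy,
        delta_se=se_y,
        trend=trend,
        trend_se=trend_se,
        first_stage=dx,
        first_stage_se=se_x,
        per_year=psi,
        per_year_se=psi_se,
        n=n,
        notes=notes,
    )
    est = EffectEstimate(
        method="ROSLA",
        outcome=outcome,
        beta=psi,
        se=psi_se,
        ci_low=psi - Z95 * psi_se,
        ci_high=psi + Z95 * psi_se,
        n=n,
        scale=scale,
        notes=notes,
    )
    return ref, est
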
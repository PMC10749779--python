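"""Specification tests and selection weighting.

Three checks mirror the study's diagnostics: a first-stage partial F
statistic for instrument strength; covariate balance ratios — the
instrument's association with a candidate confounder divided by its
association with the exposure, so instruments of different strength are
comparable; and inverse-probability weights that undo stratified
over/under-sampling of education groups (collider-bias correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DataError,
    EstimationError,
    RankDeficiencyError,
    UndefinedStatisticError,
)
from .iv import Z95

#: the study's published leaving-age stratum weights (left at 15 vs stayed on)
PUBLISHED_LEAVING_AGE_WEIGHTS: Dict[str, float] = {"left_at_15": 34.29, "stayed_past_15": 12.37}


def partial_f(
    data: pd.DataFrame,
    exposure: str,
    instruments: Sequence[str] | str,
    covariates: Sequence[str] = (),
    weight_col: Optional[str] = None,
) -> float:
    """Partial F statistic of the instrument block in the first stage.

    Regresses the exposure on instruments + covariates + constant and tests
    the instrument block via the restricted/unrestricted residual sums of
    squares.  In the single-instrument no-covariate case this reduces to
    F = r^2 (n-2) / (1 - r^2).
    """
    if isinstance(instruments, str):
        instruments = (instruments,)
    cols = [exposure, *instruments, *covariates] + ([weight_col] if weight_col else [])
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise DataError(f"missing columns: {missing}")
    d = data[list(dict.fromkeys(cols))].dropna()
    n = len(d)
    sw = np.sqrt(d[weight_col].to_numpy(dtype=float)) if weight_col else np.ones(n)
    x = d[exposure].to_numpy(dtype=float) * sw
    Z = np.column_stack(
        [d[c].to_numpy(dtype=float) for c in instruments]
        + [d[c].to_numpy(dtype=float) for c in covariates]
        + [np.ones(n)]
    ) * sw[:, None]
    q = len(instruments)
    if n <= Z.shape[1]:
        raise DataError("n must exceed the number of regressors")
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise RankDeficiencyError("instrument collinear with covariates in first stage")
    b_full, _, _, _ = np.linalg.lstsq(Z, x, rcond=None)
    rss_full = float(np.sum((x - Z @ b_full) ** 2))
    Zr = Z[:, q:]
    b_r, _, _, _ = np.linalg.lstsq(Zr, x, rcond=None)
    rss_r = float(np.sum((x - Zr @ b_r) ** 2))
    if rss_full <= 0:
        return float("inf")
    return ((rss_r - rss_full) / q) / (rss_full / (n - Z.shape[1]))


@dataclass
class BalanceStatistic:
    """Instrument-covariate association scaled by instrument strength."""

    covariate: str
    instrument: str
    assoc_covariate: float  # covariate units per unit instrument
    assoc_covariate_se: float
    assoc_exposure: float  # exposure units per unit instrument
    assoc_exposure_se: float
    ratio: float  # covariate shift per unit of exposure shifted
    ratio_se: float
    undefined: bool = False

    @property
    def ci(self):
        return (self.ratio - Z95 * self.ratio_se, self.ratio + Z95 * self.ratio_se)

    def to_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "instrument": self.instrument,
            "ratio": self.ratio,
            "se": self.ratio_se,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "assoc_covariate": self.assoc_covariate,
            "assoc_exposure": self.assoc_exposure,
            "undefined": self.undefined,
        }


def balance_ratios(
    data: pd.DataFrame,
    instrument: str,
    exposure: str,
    covariates: Sequence[str],
    weight_col: Optional[str] = None,
    instrument_label: Optional[str] = None,
) -> list:
    """Covariate balance: (instrument->covariate) / (instrument->exposure).

    Both associations are simple (weighted) regressions on the instrument,
    estimated jointly as stacked just-identified moment conditions so the
    ratio's standard error accounts for their covariance (delta method with
    the joint sandwich).  Ratios are invariant to affine rescaling of the
    instrument.  A near-zero exposure association (|t| < 2) flags the ratio
    as undefined rather than reporting a meaningless number.
    """
    label = instrument_label or instrument
    cols = [instrument, exposure, *covariates] + ([weight_col] if weight_col else [])
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise DataError(f"missing columns: {missing}")

    out = []
    for cov in covariates:
        d = data[list(dict.fromkeys([instrument, exposure, cov] + ([weight_col] if weight_col else [])))].dropna()
        w = d[weight_col].to_numpy(dtype=float) if weight_col else np.ones(len(d))
        z = d[instrument].to_numpy(dtype=float)
        x = d[exposure].to_numpy(dtype=float)
        c = d[cov].to_numpy(dtype=float)
        zbar = np.average(z, weights=w)
        zt = z - zbar
        denom = float(np.sum(w * zt * zt))
        if denom <= 0:
            raise EstimationError(f"instrument {instrument!r} has no variance")
        b_c = float(np.sum(w * zt * c) / denom)
        b_x = float(np.sum(w * zt * x) / denom)
        u = c - np.average(c, weights=w) - b_c * zt
        v = x - np.average(x, weights=w) - b_x * zt
        var_bc = float(np.sum((w * zt * u) ** 2) / denom**2)
        var_bx = float(np.sum((w * zt * v) ** 2) / denom**2)
        cov_b = float(np.sum((w * zt) ** 2 * u * v) / denom**2)
        se_bc, se_bx = np.sqrt(var_bc), np.sqrt(var_bx)
        undefined = se_bx > 0 and abs(b_x / se_bx) < 2
        if b_x == 0 or undefined:
            ratio, ratio_se, undefined = float("nan"), float("nan"), True
        else:
            ratio = b_c / b_x
            var_r = var_bc / b_x**2 + b_c**2 * var_bx / b_x**4 - 2 * b_c * cov_b / b_x**3
            ratio_se = float(np.sqrt(max(var_r, 0.0)))
        out.append(
            BalanceStatistic(
                covariate=cov,
                instrument=label,
                assoc_covariate=b_c,
                assoc_covariate_se=float(se_bc),
                assoc_exposure=b_x,
                assoc_exposure_se=float(se_bx),
                ratio=ratio,
                ratio_se=ratio_se,
                undefined=undefined,
            )
        )
    # sorted for plotting: largest standardized imbalance first
    out.sort(key=lambda s: -abs(s.ratio / s.ratio_se) if s.ratio_se and np.isfinite(s.ratio_se) and s.ratio_se > 0 else 0.0)
    return out


def compute_ipw(
    sample_counts: Mapping[str, float],
    population_fractions: Mapping[str, float],
    scale: float = 1.0,
) -> Dict[str, float]:
    """Per-stratum inverse-probability weights.

    weight(s) = scale * population_fraction(s) / sample_fraction(s).  After
    weighting, the weighted sample stratum shares equal the population shares
    exactly.  ``scale`` can carry a common factor such as the inverse overall
    sampling fraction (the study's published pair 34.29 / 12.37 for leaving
    school at 15 vs staying on includes one).
    """
    if set(sample_counts) != set(population_fractions):
        raise DataError(
            f"strata mismatch: sample {sorted(sample_counts)} vs population {sorted(population_fractions)}"
        )
    tot_pop = float(sum(population_fractions.values()))
    if not np.isclose(tot_pop, 1.0, atol=1e-6):
        raise DataError(f"population fractions must sum to 1, got {tot_pop}")
    n = float(sum(sample_counts.values()))
    if n <= 0:
        raise DataError("empty sample")
    weights = {}
    for s, cnt in sample_counts.items():
        if cnt <= 0:
            raise UndefinedStatisticError(f"empty sample stratum {s!r}: weight undefined")
        weights[s] = scale * population_fractions[s] / (cnt / n)
    return weights


def attach_ipw(
    data: pd.DataFrame,
    stratum_col: str,
    population_fractions: Mapping[str, float],
    weight_col: str = "sampling_weight",
    scale: float = 1.0,
) -> pd.DataFrame:
    """Write per-stratum IPW weights into the cohort's weight column."""
    counts = data[stratum_col].value_counts().to_dict()
    w = compute_ipw({str(k): v for k, v in counts.items()},
                    {str(k): v for k, v in population_fractions.items()}, scale=scale)
    out = data.copy()
    out[weight_col] = out[stratum_col].astype(str).map(w)
    return out
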
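"""Per-SNP sensitivity estimators probing the exclusion restriction.

Each SNP gives a Wald ratio (its outcome association over its exposure
association).  If every SNP is a valid instrument the ratios scatter around
one causal effect; pleiotropy shows up as heterogeneity (Cochran's Q), a
nonzero MR-Egger intercept (directional pleiotropy), or disagreement between
the inverse-variance-weighted mean and the weighted median (which tolerates
up to half the weight on invalid SNPs).  Leave-one-out flags single variants
that drive the pooled estimate.  Summary pairs are computed in-sample from
the one simulated cohort (one-sample design), or supplied externally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, EstimationError, InsufficientInstrumentsError
from .iv import Z95, EffectEstimate


@dataclass
class SnpWald:
    """One SNP's instrument-exposure and instrument-outcome associations."""

    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float

    @property
    def ratio(self) -> float:
        return self.beta_outcome / self.beta_exposure

    @property
    def ratio_se(self) -> float:
        """First-order SE of the per-SNP Wald ratio (se_out / |beta_exp|).

    The full second-order delta expansion adds a beta_outcome^2 term that
    would make inverse-variance weights depend on the realized outcome beta,
    biasing the pooled estimate downward; the first-order form is the
    conventional choice for IVW weighting.
        """
        return float(self.se_outcome / abs(self.beta_exposure))

    @property
    def ratio_se_delta(self) -> float:
        """Second-order delta-method SE (for reporting, not weighting)."""
        bx, by = self.beta_exposure, self.beta_outcome
        return float(
            np.sqrt(self.se_outcome**2 / bx**2 + by**2 * self.se_exposure**2 / bx**4)
        )


def snp_associations(
    dosages: pd.DataFrame,
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str,
    snp_cols: Optional[Sequence[str]] = None,
    covariates: Sequence[str] = (),
    weight_col: Optional[str] = None,
) -> pd.DataFrame:
    """Per-SNP simple-regression betas of exposure and outcome on dosage.

    ``dosages`` is the participant x SNP matrix (indexed like ``cohort``);
    exposure, outcome and dosages are first residualized on the covariates.
    Returns a summary table (snp_id, beta_exp, se_exp, beta_out, se_out)
    ready for :func:`per_snp_ratios` — the one-sample analogue of a pair of
    GWAS lookups.
    """
    snp_cols = list(snp_cols) if snp_cols is not None else [c for c in dosages.columns if c != "participant_id"]
    y = cohort[outcome].to_numpy(dtype=float)
    x = cohort[exposure].to_numpy(dtype=float)
    G = dosages[snp_cols].to_numpy(dtype=float)
    w = cohort[weight_col].to_numpy(dtype=float) if weight_col else np.ones(len(y))
    ok = np.isfinite(y) & np.isfinite(x) & np.all(np.isfinite(G), axis=1) & np.isfinite(w)
    y, x, G, w = y[ok], x[ok], G[ok], w[ok]
    n = len(y)
    sw = np.sqrt(w)

    C = np.column_stack([cohort.loc[ok, c].to_numpy(dtype=float) for c in covariates] + [np.ones(n)])
    Cw = C * sw[:, None]

    def resid(v: np.ndarray) -> np.ndarray:
        b, _, _, _ = np.linalg.lstsq(Cw, v * sw, rcond=None)
        return v * sw - Cw @ b

    yr, xr = resid(y), resid(x)
    Gr = np.empty_like(G)
    B, _, _, _ = np.linalg.lstsq(Cw, G * sw[:, None], rcond=None)
    Gr = G * sw[:, None] - Cw @ B

    ss = np.sum(Gr * Gr, axis=0)
    ss = np.where(ss > 0, ss, np.nan)
    k = C.shape[1] + 1
    bx = (Gr.T @ xr) / ss
    by = (Gr.T @ yr) / ss
    # residual variances per SNP for classical simple-regression SEs
    rx = xr[:, None] - Gr * bx[None, :]
    ry = yr[:, None] - Gr * by[None, :]
    se_x = np.sqrt(np.sum(rx * rx, axis=0) / (n - k) / ss)
    se_y = np.sqrt(np.sum(ry * ry, axis=0) / (n - k) / ss)
    return pd.DataFrame(
        {
            "snp_id": snp_cols,
            "beta_exposure": bx,
            "se_exposure": se_x,
            "beta_outcome": by,
            "se_outcome": se_y,
        }
    )


def per_snp_ratios(summary: pd.DataFrame) -> Tuple[List[SnpWald], int]:
    """Build per-SNP Wald ratios; SNPs with zero/undefined exposure beta are
    excluded and counted (second return value)."""
    req = {"snp_id", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome"}
    if not req.issubset(summary.columns):
        raise DataError(f"summary table must have columns {sorted(req)}")
    snps, n_excluded = [], 0
    for _, row in summary.iterrows():
        bx = float(row["beta_exposure"])
        if bx == 0 or not np.isfinite(bx):
            n_excluded += 1
            continue
        snps.append(
            SnpWald(
                snp_id=str(row["snp_id"]),
                beta_exposure=bx,
                se_exposure=float(row["se_exposure"]),
                beta_outcome=float(row["beta_outcome"]),
                se_outcome=float(row["se_outcome"]),
            )
        )
    if not snps:
        raise InsufficientInstrumentsError("no SNP with nonzero exposure association")
    return snps, n_excluded


def _weights(snps: Sequence[SnpWald]) -> np.ndarray:
    se = np.array([s.ratio_se for s in snps])
    if np.any(se <= 0):
        raise EstimationError("non-positive per-SNP ratio SE")
    return 1.0 / se**2


def ivw(
    snps: Sequence[SnpWald], random_effects: str = "multiplicative"
) -> Tuple[EffectEstimate, float]:
    """Inverse-variance-weighted mean of per-SNP ratios, with Cochran's Q.

    When Q exceeds its degrees of freedom and ``random_effects`` is
    "multiplicative", the SE is inflated by sqrt(Q / df) (noted on the
    estimate); "fixed" switches the inflation off.
    """
    if len(snps) < 2:
        raise InsufficientInstrumentsError("IVW needs >= 2 SNPs")
    psi = np.array([s.ratio for s in snps])
    w = _weights(snps)
    est = float(np.sum(w * psi) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (psi - est) ** 2))
    df = len(snps) - 1
    notes = ""
    if random_effects == "multiplicative" and q > df:
        se *= np.sqrt(q / df)
        notes = f"multiplicative random-effects inflation sqrt(Q/df) applied (Q={q:.1f}, df={df})"
    return (
        EffectEstimate(
            method="IVW",
            outcome="",
            beta=est,
            se=se,
            ci_low=est - Z95 * se,
            ci_high=est + Z95 * se,
            n=len(snps),
            notes=notes,
        ),
        q,
    )


def mr_egger(snps: Sequence[SnpWald]) -> Tuple[EffectEstimate, EffectEstimate]:
    """MR-Egger: weighted regression of outcome betas on exposure betas.

    SNPs are oriented so exposure betas are positive; the free intercept
    absorbs (and estimates) average directional pleiotropy, the slope is the
    pleiotropy-adjusted effect.  Weights 1 / se_outcome^2 with multiplicative
    overdispersion (SE scale never shrunk below the homoskedastic one).
    """
    if len(snps) < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 SNPs")
    sign = np.array([np.sign(s.beta_exposure) for s in snps])
    bx = np.array([s.beta_exposure for s in snps]) * sign
    by = np.array([s.beta_outcome for s in snps]) * sign
    se_y = np.array([s.se_outcome for s in snps])
    if np.ptp(bx) < 1e-12:
        raise EstimationError("exposure betas have no spread: Egger slope unidentified")
    w = 1.0 / se_y**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    XtWX_inv = np.linalg.inv(X.T @ WX)
    coef = XtWX_inv @ (WX.T @ by)
    resid = by - X @ coef
    df = len(snps) - 2
    phi = max(1.0, float(np.sum(w * resid**2) / df))  # multiplicative overdispersion
    V = XtWX_inv * phi
    inter, slope = coef
    se_i, se_s = np.sqrt(np.diag(V))
    slope_est = EffectEstimate(
        method="MR-Egger",
        outcome="",
        beta=float(slope),
        se=float(se_s),
        ci_low=float(slope - Z95 * se_s),
        ci_high=float(slope + Z95 * se_s),
        n=len(snps),
    )
    intercept_est = EffectEstimate(
        method="MR-Egger intercept",
        outcome="",
        beta=float(inter),
        se=float(se_i),
        ci_low=float(inter - Z95 * se_i),
        ci_high=float(inter + Z95 * se_i),
        n=len(snps),
    )
    return slope_est, intercept_est


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    return float(np.interp(0.5, cum, v))


def weighted_median(
    snps: Sequence[SnpWald], n_boot: int = 1000, seed: int = 0
) -> EffectEstimate:
    """Inverse-variance weighted median of the per-SNP ratios.

    Consistent when SNPs carrying >= 50% of the weight are valid instruments.
    SE by seeded parametric bootstrap over the per-SNP summary statistics.
    """
    if len(snps) < 3:
        raise InsufficientInstrumentsError("weighted median needs >= 3 SNPs")
    w = _weights(snps)
    if np.sum(w) <= 0:
        raise EstimationError("total weight is zero")
    psi = np.array([s.ratio for s in snps])
    est = _weighted_median(psi, w)

    rng = np.random.default_rng(seed)
    bx = np.array([s.beta_exposure for s in snps])
    sx = np.array([s.se_exposure for s in snps])
    by = np.array([s.beta_outcome for s in snps])
    sy = np.array([s.se_outcome for s in snps])
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs = np.where(bxs == 0, 1e-12, bxs)
        r = bys / bxs
        se_r = sy / np.abs(bxs)
        boots[b] = _weighted_median(r, 1.0 / se_r**2)
    se = float(np.std(boots, ddof=1))
    return EffectEstimate(
        method="Weighted median",
        outcome="",
        beta=est,
        se=se,
        ci_low=est - Z95 * se,
        ci_high=est + Z95 * se,
        n=len(snps),
    )


def leave_one_out(
    snps: Sequence[SnpWald], flag_multiple: float = 1.0
) -> pd.DataFrame:
    """IVW re-estimated omitting each SNP in turn.

    A SNP is flagged when dropping it moves the estimate by more than
    ``flag_multiple`` x the full-sample IVW standard error.
    """
    if len(snps) < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >= 3 SNPs")
    full, _ = ivw(snps)
    rows = []
    for i, s in enumerate(snps):
        rest = [t for j, t in enumerate(snps) if j != i]
        est, _ = ivw(rest)
        shift = est.beta - full.beta
        rows.append(
            {
                "omitted_snp": s.snp_id,
                "beta": est.beta,
                "se": est.se,
                "shift": shift,
                "flagged": bool(abs(shift) > flag_multiple * full.se),
            }
        )
    return pd.DataFrame(rows)
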
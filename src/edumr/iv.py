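"""Instrumental-variable estimators for the effect of a year of education.

All estimators share one linear-algebra core: weighted least squares /
two-stage least squares / linear GMM with heteroskedasticity-robust sandwich
covariances, optionally clustered (the study design clusters on month of
birth).  Binary outcomes are handled on the additive (risk-difference) scale
throughout — a linear probability model for the adjusted regression and an
additive structural mean model, solved by GMM, for the IV analyses — so every
method reports on the same per-year scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DataError,
    DegenerateInstrumentError,
    EstimationError,
    RankDeficiencyError,
)

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class EstimationRequest:
    """What to estimate: outcome, exposure, instruments, adjustment set."""

    outcome: str
    exposure: str = "education_years"
    instruments: Tuple[str, ...] = ("allele_score",)
    covariates: Tuple[str, ...] = ("sex", "age", "month_of_birth")
    scale: str = "continuous"  # 'continuous' | 'binary'
    weight_col: Optional[str] = None
    cluster_col: Optional[str] = "month_of_birth"
    small_sample: bool = True  # clustered small-sample correction factor

    def with_(self, **kw) -> "EstimationRequest":
        return replace(self, **kw)


@dataclass
class EffectEstimate:
    """One row of the triangulation table: the effect of +1 year of education."""

    method: str
    outcome: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    scale: str = "continuous"
    first_stage_f: Optional[float] = None
    notes: str = ""

    @property
    def beta_display(self) -> float:
        """Risk differences are reported x100 (percentage points)."""
        return self.beta * 100.0 if self.scale == "binary" else self.beta

    @property
    def pvalue(self) -> float:
        if self.se <= 0:
            return float("nan")
        return float(2 * stats.norm.sf(abs(self.beta / self.se)))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "outcome": self.outcome,
            "scale": self.scale,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "beta_display": self.beta_display,
            "n": self.n,
            "first_stage_f": self.first_stage_f,
            "notes": self.notes,
        }


# ---------------------------------------------------------------------------
# design assembly


def _check_columns(data: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise DataError(f"missing columns: {missing}")


def _design(
    data: pd.DataFrame, request: EstimationRequest, need_instruments: bool
) -> Tuple[np.ndarray, np.ndarray, Optional[np.ndarray], np.ndarray, Optional[np.ndarray], list]:
    """Assemble (y, X, Z, sqrt-weights, cluster codes, X column names)."""
    cols = [request.outcome, request.exposure, *request.covariates]
    if need_instruments:
        cols += list(request.instruments)
    if request.weight_col:
        cols.append(request.weight_col)
    if request.cluster_col:
        cols.append(request.cluster_col)
    _check_columns(data, cols)
    d = data[list(dict.fromkeys(cols))].dropna()
    if len(d) == 0:
        raise DataError("no complete rows for the requested columns")

    y = d[request.outcome].to_numpy(dtype=float)
    xnames = [request.exposure, *request.covariates, "const"]
    X = np.column_stack(
        [d[request.exposure].to_numpy(dtype=float)]
        + [d[c].to_numpy(dtype=float) for c in request.covariates]
        + [np.ones(len(d))]
    )
    Z = None
    if need_instruments:
        for c in request.instruments:
            if d[c].nunique() < 2:
                raise DegenerateInstrumentError(f"instrument {c!r} is constant in sample")
        Z = np.column_stack(
            [d[c].to_numpy(dtype=float) for c in request.instruments]
            + [d[c].to_numpy(dtype=float) for c in request.covariates]
            + [np.ones(len(d))]
        )
    if d[request.exposure].nunique() < 2:
        raise DataError(f"exposure {request.exposure!r} is constant in sample")

    _check_rank(X, xnames)
    w = (
        d[request.weight_col].to_numpy(dtype=float)
        if request.weight_col
        else np.ones(len(d))
    )
    if np.any(w <= 0):
        raise DataError("weights must be strictly positive")
    clusters = (
        pd.factorize(d[request.cluster_col])[0] if request.cluster_col else None
    )
    return y, X, Z, np.sqrt(w), clusters, xnames


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name the offending columns via the QR diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise RankDeficiencyError(f"design matrix rank deficient; collinear columns: {bad or names}")


def _cluster_meat(scores: np.ndarray, clusters: Optional[np.ndarray]) -> np.ndarray:
    """sum_g s_g s_g' where s_g sums per-observation score rows within clusters."""
    if clusters is None:
        return scores.T @ scores
    G = clusters.max() + 1
    S = np.zeros((G, scores.shape[1]))
    np.add.at(S, clusters, scores)
    return S.T @ S


def _correction(n: int, k: int, clusters: Optional[np.ndarray], small_sample: bool) -> float:
    if not small_sample:
        return 1.0
    if clusters is None:
        return n / max(n - k, 1)
    G = int(clusters.max()) + 1
    if G < 2:
        return n / max(n - k, 1)
    return (G / (G - 1)) * ((n - 1) / max(n - k, 1))


def _sandwich(
    bread: np.ndarray, scores: np.ndarray, clusters, n: int, k: int, small_sample: bool
) -> np.ndarray:
    meat = _cluster_meat(scores, clusters)
    c = _correction(n, k, clusters, small_sample)
    return c * bread @ meat @ bread


def _estimate_from(
    beta: float, se: float, method: str, request: EstimationRequest, n: int, **kw
) -> EffectEstimate:
    return EffectEstimate(
        method=method,
        outcome=request.outcome,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        n=n,
        scale=request.scale,
        **kw,
    )


# ---------------------------------------------------------------------------
# estimators


def mva_adjusted(data: pd.DataFrame, request: EstimationRequest) -> EffectEstimate:
    """Multivariable-adjusted (weighted) regression of outcome on exposure.

    Binary outcomes use a linear probability model, so the coefficient is a
    risk difference and directly comparable with the IV estimates.
    """
    y, X, _, sw, clusters, _ = _design(data, request, need_instruments=False)
    yw, Xw = y * sw, X * sw[:, None]
    XtX_inv = np.linalg.pinv(Xw.T @ Xw)
    b = XtX_inv @ (Xw.T @ yw)
    u = yw - Xw @ b
    V = _sandwich(XtX_inv, Xw * u[:, None], clusters, len(y), X.shape[1], request.small_sample)
    return _estimate_from(b[0], np.sqrt(V[0, 0]), "MVA", request, len(y))


def tsls(data: pd.DataFrame, request: EstimationRequest) -> EffectEstimate:
    """Two-stage least squares with covariates in both stages.

    Clustered robust standard errors use the second-stage projected design
    with residuals from the *actual* exposure.  The first-stage partial F for
    the instrument block is attached to the result.
    """
    y, X, Z, sw, clusters, _ = _design(data, request, need_instruments=True)
    yw, Xw, Zw = y * sw, X * sw[:, None], Z * sw[:, None]
    n, k = X.shape

    ZtZ_inv = np.linalg.pinv(Zw.T @ Zw)
    Xhat = Zw @ (ZtZ_inv @ (Zw.T @ Xw))
    XhX_inv = np.linalg.pinv(Xhat.T @ Xhat)
    if not np.isfinite(XhX_inv).all() or np.linalg.matrix_rank(Xhat) < k:
        raise DegenerateInstrumentError("first-stage rank failure: instruments do not span exposure")
    b = XhX_inv @ (Xhat.T @ yw)
    u = yw - Xw @ b
    V = _sandwich(XhX_inv, Xhat * u[:, None], clusters, n, k, request.small_sample)
    fstat = _partial_f_weighted(Xw[:, 0], Zw, len(request.instruments))
    return _estimate_from(
        b[0], np.sqrt(V[0, 0]), "MR-2SLS", request, n, first_stage_f=fstat
    )


def _partial_f_weighted(x: np.ndarray, Z: np.ndarray, n_inst: int) -> float:
    """F statistic of the leading ``n_inst`` columns of Z in the regression of x on Z."""
    n, l = Z.shape
    b_full, _, _, _ = np.linalg.lstsq(Z, x, rcond=None)
    rss_full = float(np.sum((x - Z @ b_full) ** 2))
    Zr = Z[:, n_inst:]
    if Zr.shape[1]:
        b_r, _, _, _ = np.linalg.lstsq(Zr, x, rcond=None)
        rss_r = float(np.sum((x - Zr @ b_r) ** 2))
    else:
        rss_r = float(np.sum(x**2))
    df = n - l
    if df <= 0 or rss_full <= 0:
        return float("nan")
    return ((rss_r - rss_full) / n_inst) / (rss_full / df)


def additive_smm(data: pd.DataFrame, request: EstimationRequest) -> EffectEstimate:
    """Additive structural mean model by GMM.

    Moment conditions E[Ztilde (Y - psi X - C'gamma)] = 0, where Ztilde stacks
    the covariate-residualized instruments with the covariates themselves.
    Just-identified systems solve exactly (and equal 2SLS); over-identified
    systems use two-step GMM with identity first-step weighting.  For binary
    outcomes psi is a causal risk difference.
    """
    y, X, Z, sw, clusters, _ = _design(data, request, need_instruments=True)
    yw, Xw, Zw = y * sw, X * sw[:, None], Z * sw[:, None]
    n, k = X.shape
    p = len(request.instruments)

    # residualize the instruments on covariates + constant
    C = Zw[:, p:]
    coefs, _, _, _ = np.linalg.lstsq(C, Zw[:, :p], rcond=None)
    Zt = np.column_stack([Zw[:, :p] - C @ coefs, C])
    l = Zt.shape[1]

    ZW = Zt.T @ Xw  # (l, k)
    Zy = Zt.T @ yw
    if l == k:
        try:
            theta = np.linalg.solve(ZW, Zy)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"moment Jacobian singular: {exc}") from exc
        u = yw - Xw @ theta
        bread = np.linalg.pinv(ZW)
        meat = _cluster_meat(Zt * u[:, None], clusters)
        c = _correction(n, k, clusters, request.small_sample)
        V = c * bread @ meat @ bread.T
    else:
        # two-step GMM, first step identity weighting
        A1 = np.linalg.pinv(ZW.T @ ZW)
        theta = A1 @ (ZW.T @ Zy)
        u = yw - Xw @ theta
        S = _cluster_meat(Zt * u[:, None], clusters)
        try:
            S_inv = np.linalg.inv(S)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"GMM weight matrix singular: {exc}") from exc
        M = np.linalg.pinv(ZW.T @ S_inv @ ZW)
        theta = M @ (ZW.T @ S_inv @ (Zt.T @ yw))
        u = yw - Xw @ theta
        S = _cluster_meat(Zt * u[:, None], clusters)
        S_inv = np.linalg.inv(S)
        c = _correction(n, k, clusters, request.small_sample)
        V = c * np.linalg.pinv(ZW.T @ S_inv @ ZW)
    if np.linalg.matrix_rank(ZW) < k:
        raise EstimationError("moment Jacobian singular: instruments do not identify the model")
    fstat = _partial_f_weighted(Xw[:, 0], Zw, p)
    return _estimate_from(
        theta[0], np.sqrt(V[0, 0]), "MR-SMM", request, n, first_stage_f=fstat
    )


def wald_ratio(
    reduced_beta: float,
    reduced_se: float,
    first_stage_beta: float,
    first_stage_se: float,
    covariance: float = 0.0,
    method: str = "Wald",
    outcome: str = "",
    n: int = 0,
    scale: str = "continuous",
) -> EffectEstimate:
    """Ratio of reduced-form to first-stage coefficient with delta-method SE."""
    if first_stage_beta == 0:
        raise ZeroDivisionError("first-stage beta is zero: Wald ratio undefined")
    psi = reduced_beta / first_stage_beta
    var = (
        reduced_se**2 / first_stage_beta**2
        + reduced_beta**2 * first_stage_se**2 / first_stage_beta**4
        - 2 * reduced_beta * covariance / first_stage_beta**3
    )
    se = float(np.sqrt(max(var, 0.0)))
    return EffectEstimate(
        method=method,
        outcome=outcome,
        beta=float(psi),
        se=se,
        ci_low=float(psi - Z95 * se),
        ci_high=float(psi + Z95 * se),
        n=n,
        scale=scale,
    )


def within_family_tsls(
    data: pd.DataFrame, request: EstimationRequest, family_col: str = "family_id"
) -> EffectEstimate:
    """Family-fixed-effects 2SLS on sibling pairs.

    Outcome, exposure, instruments and covariates are demeaned within family,
    which removes dynastic effects and any shared family environment; the
    remaining instrument variation is the Mendelian randomness of segregation
    between siblings.  Clustered on family.
    """
    _check_columns(data, [family_col])
    counts = data.groupby(family_col)[request.outcome].transform("size")
    d = data.loc[counts >= 2].copy()
    if len(d) == 0:
        raise DataError("no families with >= 2 offspring")
    used = list(
        dict.fromkeys(
            [request.outcome, request.exposure, *request.instruments, *request.covariates]
        )
    )
    d = d.dropna(subset=used)
    g = d.groupby(family_col)
    for c in used:
        d[c] = d[c] - g[c].transform("mean")
    for c in request.instruments:
        if float(np.abs(d[c]).max() or 0.0) < 1e-12:
            raise DegenerateInstrumentError(
                f"no within-family variance in instrument {c!r} (genetically identical siblings?)"
            )
    # covariates that are constant within families vanish; drop them
    keep_cov = tuple(c for c in request.covariates if float(np.abs(d[c]).max()) > 1e-12)
    sub = request.with_(covariates=keep_cov, cluster_col=family_col)
    est = tsls(d, sub)
    return replace(est, method="MR-within-family")
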
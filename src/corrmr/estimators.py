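"""GLS estimators for Mendelian randomization with correlated instruments.

The causal effect of an exposure on an outcome is estimated from
summary-level GWAS effects (bx_j, by_j) with outcome standard errors
sy_j, allowing the instruments to be in linkage disequilibrium. Residual
correlation is carried by the covariance

    Omega[i, j] = sy_i * sy_j * r[i, j],

with r the signed LD correlation from a reference panel. The IVW
estimator is the GLS regression of by on bx through the origin; the
Egger estimator adds a free intercept whose distance from zero measures
directional horizontal pleiotropy. Cochran's Q on the GLS residuals
quantifies remaining heterogeneity, high-leverage and outlying variants
can be excluded iteratively, and the Rucker/Bowden Q-difference rule
selects between the two estimators.

Exposure-side sampling error is ignored (the standard first-order
two-sample approximation); confidence intervals use the normal
distribution with the conventional 1.959964 multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.stats import chi2, norm

from .ld import LDMatrix

#: two-sided 95% normal quantile, fixed for reproducibility
Z_95 = 1.959964

IVW = "IVW"
EGGER = "Egger"
WALD = "Wald"


@dataclass(frozen=True)
class MRFit:
    """One estimator's causal-effect estimate and diagnostics."""

    method: str
    slope: float
    slope_se: float
    ci_low: float
    ci_high: float
    pval: float
    q_stat: float
    q_df: int
    q_pval: float | None
    n_instruments_used: int
    instrument_ids: tuple[str, ...] = ()
    excluded: tuple[tuple[str, str], ...] = ()  # (variant_id, reason)
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    selected: bool | None = None

    def __post_init__(self) -> None:
        if not self.ci_low < self.ci_high:
            raise ValueError("ci_low must be below ci_high")
        used = set(self.instrument_ids)
        if used & {vid for vid, _ in self.excluded}:
            raise ValueError("excluded ids overlap used ids")

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "slope": self.slope,
            "slope_se": self.slope_se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "q_stat": self.q_stat,
            "q_df": self.q_df,
            "q_pval": self.q_pval,
            "n_instruments_used": self.n_instruments_used,
            "instrument_ids": list(self.instrument_ids),
            "excluded": [list(e) for e in self.excluded],
            "selected": self.selected,
        }
        if self.method == EGGER:
            d.update(
                intercept=self.intercept,
                intercept_se=self.intercept_se,
                intercept_p=self.intercept_p,
            )
        return d


@dataclass(frozen=True)
class DiagnosticsConfig:
    """Leverage/outlier exclusion thresholds.

    ``outlier_chisq`` defaults to 6.63, the 0.99 quantile of chi-square
    with one degree of freedom, applied to the squared decorrelated
    standardized residual of each variant; ``leverage_multiplier`` flags
    hat-diagonal values above that multiple of their mean.
    """

    leverage_multiplier: float = 3.0
    outlier_chisq: float = 6.63
    max_iterations: int = 10

    def __post_init__(self) -> None:
        if self.leverage_multiplier <= 0 or self.outlier_chisq <= 0:
            raise ValueError("thresholds must be strictly positive")
        if self.max_iterations <= 0:
            raise ValueError("max_iterations must be positive")


def _two_sided_p(z: float) -> float:
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def _omega(sy: np.ndarray, ld: LDMatrix | None, k: int) -> np.ndarray:
    r = np.eye(k) if ld is None else np.asarray(ld.r, dtype=float)
    if r.shape != (k, k):
        raise ValueError("LD matrix does not match instrument count")
    return np.outer(sy, sy) * r


def _as_vectors(bx, by, sy):
    bx = np.atleast_1d(np.asarray(bx, dtype=float))
    by = np.atleast_1d(np.asarray(by, dtype=float))
    sy = np.atleast_1d(np.asarray(sy, dtype=float))
    if not (bx.shape == by.shape == sy.shape) or bx.ndim != 1:
        raise ValueError("bx, by, sy must be equal-length vectors")
    if np.any(sy <= 0):
        raise ValueError("sy must be positive")
    return bx, by, sy


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> MRFit:
    """Single-instrument causal estimate by/bx with first-order delta SE."""
    if bx == 0:
        raise ValueError("wald_ratio undefined for bx = 0")
    if sy <= 0 or sx <= 0:
        raise ValueError("standard errors must be positive")
    slope = by / bx
    se = sy / abs(bx)
    return MRFit(
        method=WALD,
        slope=slope,
        slope_se=se,
        ci_low=slope - Z_95 * se,
        ci_high=slope + Z_95 * se,
        pval=_two_sided_p(slope / se),
        q_stat=0.0,
        q_df=0,
        q_pval=None,
        n_instruments_used=1,
    )


def q_statistic(residuals, omega, df: int) -> tuple[float, int, float | None]:
    """Cochran's Q = r' Omega^-1 r with a chi-square p at the stated df."""
    r = np.atleast_1d(np.asarray(residuals, dtype=float))
    omega = np.asarray(omega, dtype=float)
    c = cho_factor(omega, lower=True)
    q = float(r @ cho_solve(c, r))
    p = float(chi2.sf(q, df)) if df > 0 else None
    return q, df, p


def gls_ivw(
    bx,
    by,
    sy,
    ld: LDMatrix | None = None,
    instrument_ids: tuple[str, ...] = (),
) -> MRFit:
    """GLS inverse-variance-weighted estimate with LD-aware covariance.

    slope = (bx' O^-1 bx)^-1 bx' O^-1 by with O = diag(sy) R diag(sy);
    for identity LD this reduces to the classical fixed-effect IVW
    weighted average. Q is evaluated on the fitted residuals with k - 1
    degrees of freedom.
    """
    bx, by, sy = _as_vectors(bx, by, sy)
    k = bx.size
    if k < 1:
        raise ValueError("at least one instrument required")
    omega = _omega(sy, ld, k)
    c = cho_factor(omega, lower=True)
    oi_bx = cho_solve(c, bx)
    denom = float(bx @ oi_bx)
    if denom <= 0 or not np.isfinite(denom):
        raise ValueError("singular weighting: bx' Omega^-1 bx not positive")
    slope = float(bx @ cho_solve(c, by)) / denom
    se = float(np.sqrt(1.0 / denom))
    resid = by - bx * slope
    q, q_df, q_p = q_statistic(resid, omega, k - 1)
    return MRFit(
        method=IVW,
        slope=slope,
        slope_se=se,
        ci_low=slope - Z_95 * se,
        ci_high=slope + Z_95 * se,
        pval=_two_sided_p(slope / se),
        q_stat=q,
        q_df=q_df,
        q_pval=q_p,
        n_instruments_used=k,
        instrument_ids=tuple(instrument_ids),
    )


def _orient_positive(bx, by, ld):
    """Flip variants so all bx >= 0 (flipping by and signed LD rows/cols)."""
    signs = np.where(bx < 0, -1.0, 1.0)
    ld_o = None if ld is None else ld.flip(signs)
    return bx * signs, by * signs, ld_o


def gls_egger(
    bx,
    by,
    sy,
    ld: LDMatrix | None = None,
    instrument_ids: tuple[str, ...] = (),
) -> MRFit:
    """GLS Egger regression: by on [1, bx] with LD-aware covariance.

    Variants are first oriented so every exposure effect is non-negative
    (the intercept is only meaningful under a fixed allele orientation;
    the slope is unaffected for IVW but not for Egger). The intercept
    estimates the average directional pleiotropic effect; Q uses k - 2
    degrees of freedom.
    """
    bx, by, sy = _as_vectors(bx, by, sy)
    k = bx.size
    if k < 2:
        raise ValueError("Egger regression needs at least 2 instruments")
    bx, by, ld = _orient_positive(bx, by, ld)
    omega = _omega(sy, ld, k)
    X = np.column_stack([np.ones(k), bx])
    c = cho_factor(omega, lower=True)
    oi_X = cho_solve(c, X)
    xtx = X.T @ oi_X
    cov = np.linalg.inv(xtx)
    coef = cov @ (oi_X.T @ by)
    intercept, slope = float(coef[0]), float(coef[1])
    int_se = float(np.sqrt(cov[0, 0]))
    slope_se = float(np.sqrt(cov[1, 1]))
    resid = by - X @ coef
    q, q_df, q_p = q_statistic(resid, omega, k - 2)
    return MRFit(
        method=EGGER,
        slope=slope,
        slope_se=slope_se,
        ci_low=slope - Z_95 * slope_se,
        ci_high=slope + Z_95 * slope_se,
        pval=_two_sided_p(slope / slope_se),
        q_stat=q,
        q_df=q_df,
        q_pval=q_p,
        n_instruments_used=k,
        instrument_ids=tuple(instrument_ids),
        intercept=intercept,
        intercept_se=int_se,
        intercept_p=_two_sided_p(intercept / int_se),
    )


def _design(bx: np.ndarray, model: str) -> np.ndarray:
    if model == IVW:
        return bx[:, None]
    if model == EGGER:
        return np.column_stack([np.ones(bx.size), bx])
    raise ValueError(f"unknown model {model!r}")


def hat_diagonal(bx, sy, ld: LDMatrix | None, model: str) -> np.ndarray:
    """Diagonal of the GLS hat matrix H = X (X' O^-1 X)^-1 X' O^-1.

    Its sum equals the number of regression parameters (1 for IVW, 2 for
    Egger) on any input.
    """
    bx = np.atleast_1d(np.asarray(bx, dtype=float))
    sy = np.atleast_1d(np.asarray(sy, dtype=float))
    if model == EGGER:
        signs = np.where(bx < 0, -1.0, 1.0)
        bx = bx * signs
        if ld is not None:
            ld = ld.flip(signs)
    X = _design(bx, model)
    omega = _omega(sy, ld, bx.size)
    c = cho_factor(omega, lower=True)
    oi_X = cho_solve(c, X)
    xtx_inv = np.linalg.inv(X.T @ oi_X)
    return np.einsum("ij,jk,ik->i", X, xtx_inv, oi_X)


def diagnostics(
    bx,
    by,
    sy,
    ld: LDMatrix | None,
    model: str,
    cfg: DiagnosticsConfig = DiagnosticsConfig(),
    instrument_ids: tuple[str, ...] | None = None,
) -> MRFit:
    """Iterative leverage/outlier exclusion around a GLS fit.

    At each iteration the GLS hat diagonal flags variants with leverage
    above ``leverage_multiplier`` times its mean, and the squared
    decorrelated standardized residual (elementwise square of
    L^-1 (by - yhat), L the Cholesky factor of Omega, which reduces to
    (residual/se)^2 for independent instruments) flags outliers above
    ``outlier_chisq``. Flagged variants are removed and the model refit
    until nothing is flagged, ``max_iterations`` is reached, or removal
    would leave fewer instruments than the model minimum. The returned
    fit carries the exclusion log.
    """
    bx, by, sy = _as_vectors(bx, by, sy)
    k = bx.size
    ids = tuple(instrument_ids) if instrument_ids is not None else tuple(
        f"iv{i}" for i in range(k)
    )
    if len(ids) != k:
        raise ValueError("instrument_ids length mismatch")
    min_k = 1 if model == IVW else 2
    fit_fn = gls_ivw if model == IVW else gls_egger

    keep = np.ones(k, dtype=bool)
    excluded: list[tuple[str, str]] = []
    fit = None
    for _ in range(cfg.max_iterations):
        idx = np.nonzero(keep)[0]
        sub_ids = tuple(ids[i] for i in idx)
        sub_ld = None if ld is None else ld.subset(list(sub_ids))
        fit = fit_fn(bx[idx], by[idx], sy[idx], sub_ld, instrument_ids=sub_ids)

        bxx, byy = bx[idx], by[idx]
        sub_r = None
        if model == EGGER:
            signs = np.where(bxx < 0, -1.0, 1.0)
            bxx, byy = bxx * signs, byy * signs
            if sub_ld is not None:
                sub_r = sub_ld.flip(signs)
        elif sub_ld is not None:
            sub_r = sub_ld
        X = _design(bxx, model)
        omega = _omega(sy[idx], sub_r, idx.size)
        c = cho_factor(omega, lower=True)
        oi_X = cho_solve(c, X)
        xtx_inv = np.linalg.inv(X.T @ oi_X)
        h = np.einsum("ij,jk,ik->i", X, xtx_inv, oi_X)
        coef = xtx_inv @ (oi_X.T @ byy)
        resid = byy - X @ coef
        L = cholesky(omega, lower=True)
        z = solve_triangular(L, resid, lower=True)

        lev_flag = h > cfg.leverage_multiplier * h.mean()
        out_flag = z**2 > cfg.outlier_chisq
        flagged = lev_flag | out_flag
        if not flagged.any():
            break
        if flagged.all():
            raise ValueError("diagnostics removed all instruments")
        if idx.size - int(flagged.sum()) < min_k:
            break  # removal would drop below the model minimum
        for local, j in enumerate(idx):
            if flagged[local]:
                reason = "outlier" if out_flag[local] else "leverage"
                excluded.append((ids[j], reason))
                keep[j] = False
    else:
        idx = np.nonzero(keep)[0]
        sub_ids = tuple(ids[i] for i in idx)
        sub_ld = None if ld is None else ld.subset(list(sub_ids))
        fit = fit_fn(bx[idx], by[idx], sy[idx], sub_ld, instrument_ids=sub_ids)

    return replace(fit, excluded=tuple(excluded))


def select_model(fit_ivw: MRFit, fit_egger: MRFit | None, alpha_sel: float = 0.05) -> str:
    """Rucker/Bowden Q-difference rule choosing between IVW and Egger.

    Egger is chosen when Q_IVW - Q_Egger exceeds the (1 - alpha_sel)
    quantile of chi-square with 1 df; fewer than 3 instruments force IVW
    (the 2-instrument Egger line is saturated).
    """
    if fit_egger is None or fit_ivw.n_instruments_used < 3:
        return IVW
    if set(fit_ivw.instrument_ids) != set(fit_egger.instrument_ids):
        raise ValueError("model selection requires identical instrument sets")
    threshold = float(chi2.ppf(1.0 - alpha_sel, 1))
    return EGGER if (fit_ivw.q_stat - fit_egger.q_stat) > threshold else IVW


def to_odds_ratio(slope: float, slope_se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds-scale slope into an OR with Wald 95% CI."""
    if slope_se <= 0:
        raise ValueError("slope_se must be positive")
    return (
        float(np.exp(slope)),
        float(np.exp(slope - Z_95 * slope_se)),
        float(np.exp(slope + Z_95 * slope_se)),
    )


def format_or_ci(slope: float, slope_se: float) -> str:
    """Display form 'OR 0.83, 95%CI 0.79; 0.88' (2-dp rounding)."""
    orr, lo, hi = to_odds_ratio(slope, slope_se)
    return f"OR {orr:.2f}, 95%CI {lo:.2f}; {hi:.2f}"
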
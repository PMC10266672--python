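"""Closed-form least-squares helpers.

These are thin, vectorised OLS routines used throughout the association
and variance-comparison stages. They are algebraically identical to a
full OLS fit with intercept + covariates (Frisch-Waugh partialling); a
regression test checks them against statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError, ParameterError

_EPS = 1e-12


def design_q(n: int, covariates: np.ndarray | None) -> np.ndarray:
    """Orthonormal basis (Q) of the span of [intercept, covariates]."""
    if covariates is None or covariates.size == 0:
        d = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        d = np.column_stack([np.ones(n), covariates])
    q, r = np.linalg.qr(d)
    # drop numerically dependent columns (e.g. a constant covariate)
    keep = np.abs(np.diag(r)) > _EPS * max(n, 1)
    return q[:, keep]


def residualize(m: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Residual of columns of ``m`` after projecting onto span(q)."""
    m = np.asarray(m, dtype=float)
    return m - q @ (q.T @ m)


@dataclass
class OlsResult:
    beta: float
    se: float
    t: float
    p: float
    df: int


def linear_association(
    y: np.ndarray, x: np.ndarray, covariates: np.ndarray | None = None
) -> OlsResult:
    """OLS slope of ``y`` on ``x`` adjusting for intercept + covariates."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if x.shape != (n,):
        raise ParameterError("y and x must be equal-length vectors")
    q = design_q(n, covariates)
    df = n - q.shape[1] - 1
    if df <= 0:
        raise ParameterError("not enough samples for the requested adjustment")
    yr = residualize(y, q)
    xr = residualize(x, q)
    sxx = float(xr @ xr)
    if sxx < _EPS * n:
        raise DegenerateInputError("predictor is constant after adjustment")
    beta = float(xr @ yr) / sxx
    rss = float(yr @ yr) - beta * float(xr @ yr)
    rss = max(rss, 0.0)
    se = np.sqrt(rss / df / sxx)
    if se == 0:
        t = np.inf if beta != 0 else 0.0
    else:
        t = beta / se
    p = float(np.clip(2.0 * stats.t.sf(abs(t), df), np.nextafter(0, 1), 1.0))
    return OlsResult(beta=beta, se=float(se), t=float(t), p=p, df=df)


def bulk_linear_association(
    y: np.ndarray, x_matrix: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-column OLS of ``y`` on each column of ``x_matrix``.

    Returns (beta, se, p) arrays, one entry per column. Columns that are
    constant after adjustment get beta 0, se inf, p 1.
    """
    y = np.asarray(y, dtype=float)
    x_matrix = np.asarray(x_matrix, dtype=float)
    n = y.size
    q = design_q(n, covariates)
    df = n - q.shape[1] - 1
    if df <= 0:
        raise ParameterError("not enough samples for the requested adjustment")
    yr = residualize(y, q)
    xr = residualize(x_matrix, q)
    sxx = np.einsum("ij,ij->j", xr, xr)
    sxy = xr.T @ yr
    good = sxx > _EPS * n
    beta = np.zeros(x_matrix.shape[1])
    beta[good] = sxy[good] / sxx[good]
    rss = float(yr @ yr) - beta * sxy
    rss = np.maximum(rss, 0.0)
    se = np.full_like(beta, np.inf)
    se[good] = np.sqrt(rss[good] / df / sxx[good])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = np.ones_like(beta)
    p[good] = np.clip(2.0 * stats.t.sf(np.abs(t[good]), df), np.nextafter(0, 1), 1.0)
    return beta, se, p


def ols_rss(y: np.ndarray, design: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank for OLS of y on ``design``."""
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), int(rank)


def nested_f_test(
    y: np.ndarray, extra: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float, int, int]:
    """F-test of adding ``extra`` columns to an intercept+covariate model.

    Returns (F, p, df_num, df_den).
    """
    y = np.asarray(y, dtype=float)
    extra = np.asarray(extra, dtype=float)
    if extra.ndim == 1:
        extra = extra[:, None]
    n = y.size
    q = design_q(n, covariates)
    base = q  # orthonormal reduced design
    full = np.column_stack([q, extra])
    rss0, _ = ols_rss(y, base)
    rss1, rank1 = ols_rss(y, full)
    df_num = rank1 - q.shape[1]
    df_den = n - rank1
    if df_num <= 0 or df_den <= 0:
        raise ParameterError("rank-deficient nested comparison")
    if rss1 <= 0:
        return np.inf, float(np.nextafter(0, 1)), df_num, df_den
    f = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    f = max(f, 0.0)
    p = float(np.clip(stats.f.sf(f, df_num, df_den), np.nextafter(0, 1), 1.0))
    return float(f), p, df_num, df_den


def standardize(x: np.ndarray) -> np.ndarray:
    """(x - mean) / sd with ddof 0; raises on constant input."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise DegenerateInputError("cannot standardize a constant vector")
    return (x - x.mean()) / sd
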
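"""Linear trend tests for metric time series with ARMA error structure.

Each series (one metric, one zone, one class) is regressed on calendar year
with stationary ARMA(p, q) errors, mirroring the two-stage R workflow of
``auto.arima`` followed by ``gls``:

1. ``select_error_structure`` grid-searches p, q <= 2 by small-sample
   corrected AIC (AICc) of an exact Gaussian ARMA likelihood on the OLS
   residuals.
2. ``fit_trend`` estimates the regression by restricted maximum likelihood
   (REML), building the error covariance from the ARMA autocovariance
   function on the annual lattice.  Missing years (the series have 1-4 year
   gaps) are handled exactly by selecting the observed rows/columns of the
   lattice covariance — the same marginal likelihood a state-space
   evaluation with missing observations yields.

The slope test uses the Kenward-Roger small-sample adjustment: the slope
variance is inflated for the uncertainty of the estimated covariance
parameters and referred to a t distribution with Satterthwaite degrees of
freedom.  With order (0, 0) the whole procedure collapses exactly to the OLS
t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tsa.arima_process import arma_acovf
from statsmodels.tsa.statespace.tools import constrain_stationary_univariate

__all__ = ["TrendFit", "select_error_structure", "fit_trend", "trend_table"]

MIN_OBS = 5           # fewer observations than this: no fit at all
MIN_OBS_SELECT = 8    # fewer than this: order forced to (0, 0)
MAX_ORDER = 2


@dataclass
class TrendFit:
    """GLS slope/intercept of a metric-vs-year regression with ARMA errors."""

    slope: float
    intercept: float
    slope_se: float
    pvalue: float
    df: float
    order: tuple[int, int]
    ar: tuple[float, ...]
    ma: tuple[float, ...]
    sigma2: float
    n: int
    loglik: float
    converged: bool
    year_mean: float = 0.0

    def predict(self, years: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * (np.asarray(years, float) - self.year_mean)


def _constrain(theta: np.ndarray, p: int, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Map unconstrained parameters into the stationary/invertible region."""
    ar = constrain_stationary_univariate(theta[:p]) if p else np.empty(0)
    ma = constrain_stationary_univariate(theta[p:p + q]) if q else np.empty(0)
    return np.asarray(ar), np.asarray(ma)


def _arma_corr_matrix(ar: np.ndarray, ma: np.ndarray, lag: np.ndarray) -> np.ndarray:
    """Correlation matrix of a stationary ARMA process at integer lag offsets."""
    acov = arma_acovf(np.r_[1.0, -ar], np.r_[1.0, ma], nobs=int(lag.max()) + 1)
    return (acov / acov[0])[lag]


def _prepare(years: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    years, values = years[keep], values[keep]
    if len(years) > 1 and not (np.diff(years) > 0).all():
        raise ValueError("years must be strictly increasing")
    return years, values


def select_error_structure(years: np.ndarray, values: np.ndarray,
                           max_order: int = MAX_ORDER) -> tuple[int, int]:
    """Choose the ARMA(p, q) error order for a trend regression.

    Fits OLS of value on year, then evaluates every ARMA(p, q), p, q <=
    ``max_order``, on the residuals by exact Gaussian ML and picks the
    smallest AICc; ties break toward smaller p + q, then smaller p.  Series
    shorter than 8 observations always get (0, 0).
    """
    years, values = _prepare(years, values)
    n = len(values)
    if n < MIN_OBS_SELECT:
        return (0, 0)
    x = years - years.mean()
    beta = np.polyfit(x, values, 1)
    resid = values - np.polyval(beta, x)
    lag = np.abs(years[:, None] - years[None, :]).astype(int)

    def neg_ll(theta: np.ndarray, p: int, q: int) -> float:
        try:
            ar, ma = _constrain(theta, p, q)
            R = _arma_corr_matrix(ar, ma, lag)
            c = linalg.cho_factor(R)
        except (linalg.LinAlgError, ValueError):
            return 1e10
        quad = resid @ linalg.cho_solve(c, resid)
        if quad <= 0:
            return 1e10
        s2 = quad / n
        logdet = 2.0 * np.log(np.diag(c[0])).sum()
        return 0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)

    best: tuple[float, int, int, int] | None = None
    for p in range(max_order + 1):
        for q in range(max_order + 1):
            if p + q == 0:
                nll = neg_ll(np.empty(0), 0, 0)
            else:
                # AICc gaps are O(1); coarse convergence is ample here
                res = optimize.minimize(neg_ll, np.zeros(p + q), args=(p, q),
                                        method="Nelder-Mead",
                                        options={"xatol": 1e-3, "fatol": 1e-4,
                                                 "maxfev": 80 * (p + q)})
                nll = res.fun
            k = p + q + 1  # +1 for the innovation variance
            if n - k - 1 <= 0:
                continue
            aicc = 2 * nll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            key = (aicc, p + q, p, q)
            if best is None or key < best:
                best = key
    assert best is not None
    return (best[2], best[3])


def fit_trend(years: np.ndarray, values: np.ndarray,
              order: tuple[int, int] | None = None) -> TrendFit:
    """REML GLS of metric value on calendar year with ARMA(p, q) errors.

    ``order=None`` runs :func:`select_error_structure` first.  Requires at
    least 5 non-missing observations at strictly increasing years; gaps are
    allowed and enter the likelihood through the lattice autocovariance.
    Returns a :class:`TrendFit` whose p-value is the Kenward-Roger adjusted
    two-sided t-test of zero slope.
    """
    years, values = _prepare(years, values)
    n = len(values)
    if n < MIN_OBS:
        raise ValueError(f"need >= {MIN_OBS} observations, got {n}")
    if order is None:
        order = select_error_structure(years, values)
    p, q = order
    year_mean = years.mean()
    X = np.column_stack([np.ones(n), years - year_mean])
    k = X.shape[1]
    lag = np.abs(years[:, None] - years[None, :]).astype(int)

    def reml_pieces(theta: np.ndarray):
        ar, ma = _constrain(theta, p, q)
        R = _arma_corr_matrix(ar, ma, lag)
        c = linalg.cho_factor(R)
        Ri_y = linalg.cho_solve(c, values)
        Ri_X = linalg.cho_solve(c, X)
        XtRiX = X.T @ Ri_X
        beta = linalg.solve(XtRiX, X.T @ Ri_y, assume_a="pos")
        r = values - X @ beta
        s2 = (r @ linalg.cho_solve(c, r)) / (n - k)
        return R, c, beta, s2, XtRiX

    def neg_reml(theta: np.ndarray) -> float:
        try:
            R, c, beta, s2, XtRiX = reml_pieces(theta)
        except (linalg.LinAlgError, ValueError):
            return 1e10
        if s2 <= 0:
            return 1e10
        logdetR = 2.0 * np.log(np.diag(c[0])).sum()
        sign, logdetX = np.linalg.slogdet(XtRiX)
        if sign <= 0:
            return 1e10
        return 0.5 * ((n - k) * np.log(2 * np.pi * s2) + logdetR + logdetX + (n - k))

    converged = True
    if p + q:
        res = optimize.minimize(neg_reml, np.zeros(p + q), method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8})
        theta = res.x
        converged = bool(res.success)
        if not converged:
            warnings.warn(f"REML optimisation did not converge for order {order}",
                          stacklevel=2)
    else:
        theta = np.empty(0)
    R, c, beta, s2, XtRiX = reml_pieces(theta)
    ar, ma = _constrain(theta, p, q)
    loglik = -neg_reml(theta)

    scale = max(float(np.abs(values).max()), 1.0)
    if np.sqrt(max(s2, 0.0)) < 1e-10 * scale:
        # numerically exact fit (constant or perfectly linear series)
        slope_se, dof = 0.0, float(n - k)
        pvalue = 1.0 if abs(beta[1]) <= 1e-10 * scale else 0.0
    else:
        slope_var, dof = _kenward_roger(theta, p, q, lag, X, R, s2, XtRiX)
        slope_se = float(np.sqrt(slope_var))
        tstat = beta[1] / slope_se
        pvalue = float(2 * stats.t.sf(abs(tstat), df=dof))
    return TrendFit(
        slope=float(beta[1]), intercept=float(beta[0]), slope_se=slope_se,
        pvalue=pvalue, df=float(dof), order=(p, q),
        ar=tuple(np.round(ar, 10)), ma=tuple(np.round(ma, 10)),
        sigma2=float(s2), n=n, loglik=float(loglik), converged=converged,
        year_mean=float(year_mean),
    )


def _kenward_roger(theta: np.ndarray, p: int, q: int, lag: np.ndarray,
                   X: np.ndarray, R: np.ndarray, s2: float,
                   XtRiX: np.ndarray) -> tuple[float, float]:
    """Adjusted slope variance and Satterthwaite df for the GLS slope test.

    Covariance parameters are gamma = (theta_1..theta_{p+q}, sigma^2) with
    V = sigma^2 R(theta).  The slope variance is inflated by the
    Kenward-Roger correction using the expected REML information of gamma;
    the degrees of freedom follow Giesbrecht-Burns/Satterthwaite.  For order
    (0, 0) this reduces exactly to the OLS t-test with n - k df.
    """
    n, k = X.shape
    V = s2 * R
    # dV/dgamma by central differences on theta, analytic in sigma^2
    dV: list[np.ndarray] = []
    eps = 1e-5
    for i in range(p + q):
        hi, lo = theta.copy(), theta.copy()
        hi[i] += eps
        lo[i] -= eps
        ar_h, ma_h = _constrain(hi, p, q)
        ar_l, ma_l = _constrain(lo, p, q)
        dR = (_arma_corr_matrix(ar_h, ma_h, lag) - _arma_corr_matrix(ar_l, ma_l, lag)) / (2 * eps)
        dV.append(s2 * dR)
    dV.append(R)

    Vinv = np.linalg.inv(V)
    Phi = np.linalg.inv(X.T @ Vinv @ X)
    Pproj = Vinv - Vinv @ X @ Phi @ X.T @ Vinv
    m = len(dV)
    info = np.empty((m, m))
    PV = [Pproj @ d for d in dV]
    for i in range(m):
        for j in range(i, m):
            info[i, j] = info[j, i] = 0.5 * np.trace(PV[i] @ PV[j])
    try:
        W = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        W = np.linalg.pinv(info)

    Pi = [X.T @ Vinv @ d @ Vinv @ X for d in dV]
    adj = np.zeros((k, k))
    for i in range(m):
        for j in range(m):
            Qij = X.T @ Vinv @ dV[i] @ Vinv @ dV[j] @ Vinv @ X
            adj += W[i, j] * (Qij - Pi[i] @ Phi @ Pi[j])
    Phi_adj = Phi + 2 * Phi @ adj @ Phi

    cvec = np.zeros(k)
    cvec[1] = 1.0
    slope_var = float(cvec @ Phi_adj @ cvec)
    base_var = float(cvec @ Phi @ cvec)
    grad = np.array([cvec @ Phi @ Pi[i] @ Phi @ cvec for i in range(m)])
    denom = float(grad @ W @ grad)
    dof = 2 * base_var**2 / denom if denom > 0 else n - k
    dof = float(np.clip(dof, 1.0, n - k))
    if slope_var <= 0:
        slope_var = base_var
    return slope_var, dof


def trend_table(metrics_long: pd.DataFrame | None = None,
                rid_df: pd.DataFrame | None = None,
                alpha: float = 0.05,
                bh_correct: bool = False,
                max_order: int = MAX_ORDER) -> pd.DataFrame:
    """One trend fit per series: (site, zone, class, metric) and per RID zone.

    Metric input is the long table from :func:`landfrag.metrics.metrics_long`;
    RID input the table from :func:`landfrag.change.rid_series` (regressed on
    interval end year).  Series with fewer than 5 observations, or all
    missing, are skipped with a ``skipped`` reason row omitted from the
    output but noted via a warning.  ``bh_correct`` adds a
    Benjamini-Hochberg adjusted p-value column across the whole table.
    """
    rows = []
    if metrics_long is not None:
        keys = [c for c in ("site", "zone", "class", "metric") if c in metrics_long.columns]
        for key, grp in metrics_long.groupby(keys, dropna=False):
            key = key if isinstance(key, tuple) else (key,)
            info = dict(zip(keys, key))
            rows.append((info, grp["year"].to_numpy(), grp["value"].to_numpy()))
    if rid_df is not None:
        keys = [c for c in ("site", "zone") if c in rid_df.columns]
        for key, grp in rid_df.groupby(keys, dropna=False):
            key = key if isinstance(key, tuple) else (key,)
            info = dict(zip(keys, key))
            info["metric"] = "RID"
            rows.append((info, grp["interval_end"].to_numpy(), grp["RID"].to_numpy()))

    out = []
    for info, years, values in rows:
        finite = np.isfinite(np.asarray(values, float))
        if finite.sum() < MIN_OBS:
            warnings.warn(f"series {info} skipped: only {int(finite.sum())} observations",
                          stacklevel=2)
            continue
        order = select_error_structure(years, values, max_order)
        fit = fit_trend(years, values, order)
        rec = dict(info)
        rec.update({
            "slope": fit.slope, "se": fit.slope_se, "p_value": fit.pvalue,
            "ar_order": fit.order[0], "ma_order": fit.order[1], "n": fit.n,
            "df": fit.df, "converged": fit.converged,
        })
        out.append(rec)
    table = pd.DataFrame(out)
    if len(table):
        if bh_correct:
            table["p_adj"] = multipletests(table["p_value"], method="fdr_bh")[1]
        pcol = "p_adj" if bh_correct else "p_value"
        table["significant"] = table[pcol] < alpha
        table["direction"] = np.where(table["slope"] > 0, "+", "-")
    return table
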
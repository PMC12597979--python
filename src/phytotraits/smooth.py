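"""Penalized-spline (GAM-style) trait responses and linearity by EDF.

Trait responses to the opposing experimental gradient (P*, K_s, μ_max
against temperature; AUTPC and E_a against phosphorus) are fit as Gaussian
penalized regression splines: a natural cubic spline basis of dimension
``k`` (default 3, knots at the quantiles of the observed gradient) with an
integrated-squared-second-derivative penalty whose smoothing parameter is
chosen by restricted maximum likelihood (REML).  The effective degrees of
freedom (EDF) of the smooth measure how far the fit is from a straight
line: EDF ≈ 1 is linear, larger values (the classification threshold
defaults to 1.5) indicate curvature.

The smooth-term p-value is an approximate F-test of the penalized fit
against the intercept-only model on (EDF, n − EDF_total) degrees of
freedom; like all GAM smooth-term tests it is approximate and should be
read as indicative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import CubicSpline


@dataclass
class SmoothFitSummary:
    """Summary of one penalized-spline trait-response fit."""

    edf: float                 # effective degrees of freedom of the smooth
    edf_total: float           # including the intercept
    p_value: float
    deviance_explained: float
    lambda_: float             # selected smoothing parameter
    predictions: pd.DataFrame  # columns x, fit, se
    linearity: str             # 'linear' or 'nonlinear'


def _natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural-cubic-spline cardinal basis evaluated at x (n x k)."""
    cols = []
    for i in range(knots.size):
        e = np.zeros(knots.size)
        e[i] = 1.0
        cols.append(CubicSpline(knots, e, bc_type="natural")(x))
    return np.column_stack(cols)


def _wiggliness_penalty(knots: np.ndarray) -> np.ndarray:
    """Integrated squared second derivative of a natural cubic spline,
    as a quadratic form K in the values at the knots: K = D' W^-1 D."""
    h = np.diff(knots)
    k = knots.size
    D = np.zeros((k - 2, k))
    W = np.zeros((k - 2, k - 2))
    for j in range(k - 2):
        D[j, j] = 1.0 / h[j]
        D[j, j + 1] = -1.0 / h[j] - 1.0 / h[j + 1]
        D[j, j + 2] = 1.0 / h[j + 1]
        W[j, j] = (h[j] + h[j + 1]) / 3.0
        if j + 1 < k - 2:
            W[j, j + 1] = W[j + 1, j] = h[j + 1] / 6.0
    return D.T @ np.linalg.solve(W, D)


def _reml_criterion(log_lam, X, y, S, d_pos, n):
    """Negative restricted log-likelihood (profiled scale), up to a
    constant: (n − M_p)·log(P) + log|X'X + λS| − rank(S)·log λ."""
    lam = np.exp(log_lam)
    A = X.T @ X + lam * S
    try:
        beta = np.linalg.solve(A, X.T @ y)
    except np.linalg.LinAlgError:
        return np.inf
    resid = y - X @ beta
    pen_rss = float(resid @ resid + lam * beta @ S @ beta)
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0 or pen_rss <= 0:
        return np.inf
    m_null = X.shape[1] - d_pos.size
    return ((n - m_null) * np.log(pen_rss) + logdet
            - d_pos.size * log_lam - float(np.sum(np.log(d_pos))))


def fit_smooth(x, y, k: int = 3,
               linearity_threshold: float = 1.5) -> SmoothFitSummary:
    """Fit a Gaussian penalized regression spline of y on x.

    Knots sit at the quantiles of the distinct x values; the smooth is
    centered (sum-to-zero over the data) and an unpenalized intercept is
    added, so the penalty null space is exactly the linear trend and
    EDF of the smooth runs from 1 (straight line) to k − 1 (unpenalized).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    ux = np.unique(x)
    if ux.size < k + 1:
        raise ValueError(f"need at least {k + 1} distinct x values "
                         f"(got {ux.size})")
    n = x.size
    knots = np.quantile(ux, np.linspace(0, 1, k))
    B = _natural_spline_basis(x, knots)
    K = _wiggliness_penalty(knots)

    # sum-to-zero constraint over the data, absorbed by reparameterization
    C = B.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(C)
    Z = vt[1:].T                                   # k x (k-1)
    X = np.column_stack([np.ones(n), B @ Z])
    Sz = Z.T @ K @ Z
    S = np.zeros((k, k))
    S[1:, 1:] = Sz
    eig = np.linalg.eigvalsh(Sz)
    d_pos = eig[eig > eig.max() * 1e-10]

    # REML's scale profile degenerates when a plain line already fits the
    # data (residual variance ~ 0); the penalty cannot improve on it, so
    # return the straight-line fit (EDF = 1) directly.
    tss = float(np.sum((y - y.mean()) ** 2))
    Xl = np.column_stack([np.ones(n), x])
    bl, *_ = np.linalg.lstsq(Xl, y, rcond=None)
    rss_l = float(np.sum((y - Xl @ bl) ** 2))
    if tss == 0 or rss_l <= 1e-10 * max(tss, 1.0):
        fitted = Xl @ bl
        sigma2 = rss_l / max(n - 2, 1)
        Vl = sigma2 * np.linalg.inv(Xl.T @ Xl)
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xl, Vl, Xl), 0.0))
        if tss == 0:
            p_value, dev = 1.0, 0.0
        else:
            f_stat = ((tss - rss_l) / 1.0) / max(rss_l / max(n - 2, 1), 1e-300)
            p_value = float(stats.f.sf(f_stat, 1, max(n - 2, 1)))
            dev = 1.0 - rss_l / tss
        preds = pd.DataFrame({"x": x, "fit": fitted, "se": se})
        return SmoothFitSummary(edf=1.0, edf_total=2.0, p_value=p_value,
                                deviance_explained=float(dev),
                                lambda_=float("inf"), predictions=preds,
                                linearity=classify_linearity(
                                    1.0, linearity_threshold))

    grid = np.linspace(-12.0, 18.0, 61)
    scores = [_reml_criterion(g, X, y, S, d_pos, n) for g in grid]
    g0 = grid[int(np.argmin(scores))]
    res = optimize.minimize_scalar(_reml_criterion, bounds=(g0 - 1.5, g0 + 1.5),
                                   args=(X, y, S, d_pos, n), method="bounded")
    lam = float(np.exp(res.x))

    A = X.T @ X + lam * S
    Ainv = np.linalg.inv(A)
    beta = Ainv @ X.T @ y
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    edf_total = float(np.trace(Ainv @ (X.T @ X)))
    edf = edf_total - 1.0

    sigma2 = rss / max(n - edf_total, 1e-8)
    Vb = sigma2 * Ainv
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, Vb, X), 0.0))

    if tss > 0 and rss < tss and n - edf_total > 0:
        f_stat = ((tss - rss) / max(edf, 1e-8)) / (rss / (n - edf_total)) \
            if rss > 0 else np.inf
        p_value = float(stats.f.sf(f_stat, max(edf, 1e-8), n - edf_total))
    elif tss == 0:
        p_value = 1.0
    else:
        p_value = 1.0
    dev_expl = 1.0 - rss / tss if tss > 0 else 0.0

    preds = pd.DataFrame({"x": x, "fit": fitted, "se": se})
    return SmoothFitSummary(edf=edf, edf_total=edf_total, p_value=p_value,
                            deviance_explained=float(dev_expl), lambda_=lam,
                            predictions=preds,
                            linearity=classify_linearity(
                                max(edf, 1.0), linearity_threshold))


def classify_linearity(edf: float, threshold: float = 1.5) -> str:
    """'linear' below the EDF threshold, 'nonlinear' at or above it."""
    if edf < 1 - 1e-6:
        raise ValueError("edf below 1 is outside the smooth's range")
    return "linear" if edf < threshold else "nonlinear"


def trait_smooth_table(df: pd.DataFrame, trait_col: str, gradient_col: str,
                       by: str = "strain", k: int = 3,
                       min_points: int = 4) -> pd.DataFrame:
    """Fit one smooth per group and tabulate EDF / p / deviance explained.

    Groups with too few usable points (fewer than ``min_points`` finite
    trait values, mirroring strains whose trait could be estimated at only
    a few levels) are reported with NaN summaries rather than fitted.
    """
    rows = []
    for key, g in df.groupby(by, sort=True):
        xs = g[gradient_col].to_numpy(dtype=float)
        ys = g[trait_col].to_numpy(dtype=float)
        usable = np.isfinite(xs) & np.isfinite(ys)
        row = {by: key, "trait": trait_col, "gradient": gradient_col,
               "n": int(usable.sum())}
        if usable.sum() >= min_points and np.unique(xs[usable]).size >= k + 1:
            fit = fit_smooth(xs[usable], ys[usable], k=k)
            row.update(edf=fit.edf, p_value=fit.p_value,
                       deviance_explained=fit.deviance_explained,
                       linearity=fit.linearity)
        else:
            row.update(edf=np.nan, p_value=np.nan,
                       deviance_explained=np.nan, linearity="not_fitted")
        rows.append(row)
    return pd.DataFrame(rows)
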
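"""Monod growth kinetics and minimal phosphorus requirements (P*).

Growth along a resource gradient follows the Monod (saturating) form

    μ(S) = μ_max * S / (K_s + S)

with half-saturation constant K_s.  Resource-competition (R*) theory gives
the minimal resource concentration at which growth balances a fixed
mortality rate m:

    P* = K_s * m / (μ_max − m)

Strains with lower P* are superior competitors under resource limitation.
Negative K_s or P* estimates (which arise when growth barely responds to
the gradient) are not biologically meaningful and are flagged for
exclusion from downstream trait analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

DEFAULT_MORTALITY = 0.1
"""Mortality / loss rate m (day⁻¹) used to derive P* from Monod fits."""

#: default parameter box (low, high) for (mu_max, Ks); generous biological
#: ranges with a boundary-hit flag replacing any data-driven tightening.
DEFAULT_MONOD_BOUNDS = ((1e-8, 5.0), (1e-4, 100.0))


def monod(S, mu_max, ks):
    """Monod growth rate at substrate concentration(s) ``S``."""
    S = np.asarray(S, dtype=float)
    return mu_max * S / (ks + S)


def pstar(ks: float, mu_max: float, m: float = DEFAULT_MORTALITY) -> float:
    """Minimal resource requirement P* = K_s·m/(μ_max − m).

    Raises on μ_max == m (the requirement diverges).  Negative values are
    returned as-is; validity is decided by :func:`validate_monod`.
    """
    if mu_max == m:
        raise ValueError("p_star undefined at mu_max == m")
    return ks * m / (mu_max - m)


@dataclass
class MonodFit:
    """Fitted Monod curve with derived P* and a biological-validity flag."""

    mu_max: float
    ks: float
    m: float
    p_star: float
    rss: float
    n: int
    valid: bool
    boundary_hit: bool = False
    ok: bool = True
    message: str = ""
    ci: dict = field(default=None, repr=False)

    def __call__(self, S):
        return monod(S, self.mu_max, self.ks)


def _assess_validity(mu_max, ks, p_star, m, boundary_hit):
    return bool(ks > 0 and p_star > 0 and mu_max > m and not boundary_hit)


def fit_monod(phosphorus, rates, n_starts: int = 30, seed=None,
              bounds=DEFAULT_MONOD_BOUNDS, m: float = DEFAULT_MORTALITY,
              include_negative_rates: bool = True,
              extra_starts=()) -> MonodFit:
    """Fit μ = μ_max·S/(K_s+S) by multi-start nonlinear least squares.

    A heuristic start (μ_max ≈ max observed rate, K_s ≈ median S) is always
    included along with ``n_starts`` random starts drawn within ``bounds``
    (K_s log-uniformly).  Negative rates are included by default — the Monod
    form cannot go below zero, so they penalize the low-S part of the fit —
    but can be dropped with ``include_negative_rates=False``.

    A fit whose K_s lands on the lower bound is returned with
    ``boundary_hit=True`` and ``valid=False`` (flat-curve degeneracy).
    """
    S = np.asarray(phosphorus, dtype=float)
    mu = np.asarray(rates, dtype=float)
    if S.shape != mu.shape:
        raise ValueError("phosphorus and rates must have the same length")
    if not include_negative_rates:
        keep = mu > 0
        S, mu = S[keep], mu[keep]
    if np.unique(S).size < 3:
        raise ValueError("need at least 3 distinct substrate levels")

    (mu_lo, mu_hi), (ks_lo, ks_hi) = bounds
    lo = np.array([mu_lo, ks_lo])
    hi = np.array([mu_hi, ks_hi])
    rng = np.random.default_rng(seed)
    mu_top = float(np.clip(mu.max(), mu_lo * 2, mu_hi))
    starts = [np.array([mu_top, float(np.median(S))])]
    starts.extend(np.asarray(s, dtype=float) for s in extra_starts)
    if n_starts > 0:
        draw_mu = rng.uniform(mu_lo, mu_hi, n_starts)
        draw_ks = np.exp(rng.uniform(np.log(ks_lo), np.log(ks_hi), n_starts))
        starts.extend(np.column_stack([draw_mu, draw_ks]))

    def resid(params):
        return monod(S, params[0], params[1]) - mu

    def jac(params):
        mu_max, ks = params
        frac = S / (ks + S)
        return np.column_stack([frac, -mu_max * frac / (ks + S)])

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            res = optimize.least_squares(resid, x0, jac=jac,
                                         bounds=(lo, hi), method="trf")
        except Exception:
            continue
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        return MonodFit(np.nan, np.nan, m, np.nan, np.inf, S.size,
                        valid=False, ok=False,
                        message="optimizer failed from every start")
    rss, (mu_max, ks) = best
    mu_max, ks = float(mu_max), float(ks)
    boundary = ks <= ks_lo * (1 + 1e-6) or ks >= ks_hi * (1 - 1e-6)
    ps = pstar(ks, mu_max, m) if mu_max != m else float("nan")
    return MonodFit(mu_max, ks, m, float(ps), rss, int(S.size),
                    valid=_assess_validity(mu_max, ks, ps, m, boundary),
                    boundary_hit=bool(boundary))


@dataclass
class MonodBootstrap:
    """Percentile bootstrap intervals for Monod parameters and P*."""

    ci_mu_max: tuple
    ci_ks: tuple
    ci_p_star: tuple
    mean_p_star: float
    mu_max_values: np.ndarray
    ks_values: np.ndarray
    p_star_values: np.ndarray
    n_effective: int
    n_skipped: int


def bootstrap_monod(phosphorus, rates, B: int = 1000, seed=None,
                    m: float = DEFAULT_MORTALITY, n_starts: int = 5,
                    bounds=DEFAULT_MONOD_BOUNDS) -> MonodBootstrap:
    """Nonparametric case-resampling bootstrap of the Monod fit.

    Each resample draws n observations with replacement from the (S, μ)
    pairs, refits the Monod curve (starting from the point estimate plus a
    few random starts) and collects μ_max, K_s and the derived P*.
    Intervals are the 2.5/97.5 percentiles; the bootstrap-mean P* is
    reported for comparison with the point estimate.  Resamples with < 3
    distinct levels or failed fits are skipped and counted.  (Unstratified
    resampling is deliberate: per-level stratification shrinks resample
    variability and measurably undercovers.)
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    S = np.asarray(phosphorus, dtype=float)
    mu = np.asarray(rates, dtype=float)
    rng = np.random.default_rng(seed)
    point = fit_monod(S, mu, n_starts=20, seed=rng.integers(2 ** 31),
                      bounds=bounds, m=m)
    extra = [(point.mu_max, point.ks)] if point.ok else []

    mm, kk, pp, skipped = [], [], [], 0
    for _ in range(B):
        idx = rng.choice(S.size, size=S.size, replace=True)
        if np.unique(S[idx]).size < 3:
            skipped += 1
            continue
        try:
            refit = fit_monod(S[idx], mu[idx], n_starts=n_starts,
                              seed=rng.integers(2 ** 31), bounds=bounds, m=m,
                              extra_starts=extra)
        except ValueError:
            skipped += 1
            continue
        if not refit.ok:
            skipped += 1
            continue
        mm.append(refit.mu_max)
        kk.append(refit.ks)
        pp.append(refit.p_star)
    mm, kk, pp = np.array(mm), np.array(kk), np.array(pp)

    def ci(v):
        return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))

    finite_p = pp[np.isfinite(pp)]
    return MonodBootstrap(ci(mm), ci(kk), ci(finite_p),
                          float(finite_p.mean()), mm, kk, pp,
                          len(mm), skipped)


@dataclass
class ExclusionRecord:
    """Outcome of the biological-validity screen of a Monod fit."""

    retained: bool
    retain_mu_max: bool
    reasons: tuple


def validate_monod(fit: MonodFit) -> ExclusionRecord:
    """Screen a Monod fit for biologically meaningful K_s and P*.

    Fits with negative K_s or P*, with μ_max ≤ m (growth cannot balance
    mortality anywhere), or with K_s pinned at a parameter bound are
    excluded from K_s/P* trait analyses.  μ_max is retained whenever the
    fit itself converged.
    """
    reasons = []
    if not fit.ok:
        reasons.append("fit failed")
    else:
        if fit.ks <= 0:
            reasons.append("non-positive Ks")
        if not np.isfinite(fit.p_star) or fit.p_star <= 0:
            reasons.append("non-positive p_star")
        if fit.mu_max <= fit.m:
            reasons.append("mu_max does not exceed mortality")
        if fit.boundary_hit:
            reasons.append("Ks at parameter bound")
    return ExclusionRecord(retained=not reasons,
                           retain_mu_max=fit.ok,
                           reasons=tuple(reasons))
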
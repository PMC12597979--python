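"""Thermal performance curves, AUTPC and Arrhenius activation energies.

The thermal performance curve (TPC) model is the Thomas-2012 form: an
exponential envelope multiplied by a downward-opening quadratic,

    R(T) = a * exp(b*T) * (1 - ((T - T_ref) / (w/2))**2)

where ``w`` is the thermal niche width (the curve has structural zeros at
``T_ref ± w/2``) and ``a``, ``b`` are scaling parameters.  From a fitted
curve we derive the optimum temperature ``T_opt``, the area under the curve
over the experimental temperature range (AUTPC, trapezoidal rule), and —
from the rising part of the curve — the Arrhenius activation energy of
population growth,

    R = A * exp(-Ea / (k*T_kelvin)),   k = 8.62e-5 eV/K,

estimated as minus the OLS slope of ln(R) on 1/(k*T_kelvin).  With this
sign convention growth that accelerates with temperature yields Ea > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

K_BOLTZMANN = 8.62e-5
"""Boltzmann constant in eV·K⁻¹."""

EA_REFERENCE = 0.32
"""Reference activation energy (eV) expected from the temperature
sensitivity of Rubisco carboxylation in C3 photoautotrophs."""

#: default multi-start sampling box: (low, high) per parameter (a, b, T_ref, w)
DEFAULT_TPC_BOUNDS = ((1e-8, 10.0), (-1.0, 1.0), (0.0, 40.0), (5.0 + 1e-8, 80.0))


def thomas_tpc(T, a, b, t_ref, w):
    """Evaluate the Thomas-2012 TPC at temperature(s) ``T`` (°C)."""
    T = np.asarray(T, dtype=float)
    u = (T - t_ref) / (w / 2.0)
    return a * np.exp(b * T) * (1.0 - u * u)


@dataclass
class TPCFit:
    """Fitted Thomas-2012 thermal performance curve."""

    a: float
    b: float
    t_ref: float
    w: float
    rss: float
    n: int
    ok: bool = True
    message: str = ""

    @property
    def t_opt(self) -> float:
        return tpc_topt(self)

    def __call__(self, T):
        return thomas_tpc(T, self.a, self.b, self.t_ref, self.w)


def _tpc_residuals(params, T, mu):
    a, b, t_ref, w = params
    return thomas_tpc(T, a, b, t_ref, w) - mu


def _tpc_jacobian(params, T, mu):
    a, b, t_ref, w = params
    h = w / 2.0
    u = (T - t_ref) / h
    env = np.exp(b * T)
    quad = 1.0 - u * u
    return np.column_stack([
        env * quad,                    # d/da
        T * a * env * quad,            # d/db
        a * env * 2.0 * u / h,         # d/dT_ref
        a * env * 2.0 * u * u / w,     # d/dw
    ])


def fit_tpc(temperatures, rates, n_starts: int = 250, seed=None,
            bounds=DEFAULT_TPC_BOUNDS, extra_starts=()) -> TPCFit:
    """Fit the Thomas-2012 TPC by multi-start nonlinear least squares.

    Starting values are drawn uniformly within ``bounds`` from a generator
    seeded with ``seed``; one documented deterministic start (a=0.2, b=0.05,
    T_ref=mean(T), w=2.5*range(T)) is always included, so the returned fit
    is never worse than that single start.  Negative rates are legitimate
    observations and enter the least squares untouched.

    Parameters
    ----------
    temperatures, rates : array-like
        Paired (°C, day⁻¹) observations; ≥ 4 distinct temperatures required.
    n_starts : int
        Number of random multi-start draws.
    extra_starts : sequence of 4-tuples
        Additional deterministic starts (used by the bootstrap to seed
        refits from the point estimate).
    """
    T = np.asarray(temperatures, dtype=float)
    mu = np.asarray(rates, dtype=float)
    if T.shape != mu.shape:
        raise ValueError("temperatures and rates must have the same length")
    if np.unique(T).size < 4:
        raise ValueError("need at least 4 distinct temperatures to fit a TPC")
    if np.all(mu <= 0):
        return TPCFit(np.nan, np.nan, np.nan, np.nan, np.inf, T.size,
                      ok=False, message="all growth rates non-positive")

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    rng = np.random.default_rng(seed)
    t_span = max(T.max() - T.min(), 1.0)
    starts = [np.array([0.2, 0.05, T.mean(), 2.5 * t_span])]
    starts.extend(np.asarray(s, dtype=float) for s in extra_starts)
    if n_starts > 0:
        draws = rng.uniform(lo, hi, size=(n_starts, 4))
        starts.extend(draws)

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            res = optimize.least_squares(_tpc_residuals, x0, args=(T, mu),
                                         jac=_tpc_jacobian,
                                         bounds=(lo, hi), method="trf")
        except Exception:
            continue
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        return TPCFit(np.nan, np.nan, np.nan, np.nan, np.inf, T.size,
                      ok=False, message="optimizer failed from every start")
    rss, (a, b, t_ref, w) = best
    return TPCFit(float(a), float(b), float(t_ref), float(w), rss, T.size)


def tpc_topt(fit) -> float:
    """Optimum temperature of a fitted TPC (closed form).

    Setting dR/dT = 0 gives, with h = w/2,

        T_opt = T_ref + b*h**2 / (1 + sqrt(1 + (b*h)**2))

    which is algebraically equal to T_ref + (sqrt(1 + b²h²) − 1)/b but
    remains finite and continuous at b = 0 (where T_opt = T_ref).
    """
    h = fit.w / 2.0
    bh = fit.b * h
    return fit.t_ref + fit.b * h * h / (1.0 + math.sqrt(1.0 + bh * bh))


def autpc(fit, t_min: float = 12.0, t_max: float = 26.0,
          grid_step: float = 0.1) -> float:
    """Area under the fitted TPC over [t_min, t_max], trapezoidal rule.

    The curve is evaluated on a uniform grid whose endpoints hit t_min and
    t_max exactly.  ``fit`` may be a :class:`TPCFit` or any callable R(T).
    """
    if t_min >= t_max:
        raise ValueError("t_min must be below t_max")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    n = int(round((t_max - t_min) / grid_step)) + 1
    grid = np.linspace(t_min, t_max, max(n, 2))
    curve = fit(grid)
    return float(np.trapezoid(curve, grid))


@dataclass
class TPCBootstrap:
    """Percentile bootstrap band for a TPC and its AUTPC."""

    grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    autpc_interval: tuple
    autpc_values: np.ndarray
    n_effective: int
    n_skipped: int


def bootstrap_tpc(temperatures, rates, B: int = 1000, seed=None,
                  n_starts: int = 15, t_min: float = 12.0, t_max: float = 26.0,
                  grid_step: float = 0.1) -> TPCBootstrap:
    """Nonparametric case-resampling bootstrap of the TPC.

    Each resample draws n observations with replacement from the (T, μ)
    pairs, the curve is refit, and the pointwise 2.5/97.5 percentiles of
    the refitted curves form the 95% band.  Refits start from the point
    estimate plus ``n_starts`` random draws.  Resamples with fewer than 4
    distinct temperatures or a non-estimable fit are skipped and counted.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    T = np.asarray(temperatures, dtype=float)
    mu = np.asarray(rates, dtype=float)
    rng = np.random.default_rng(seed)
    point = fit_tpc(T, mu, n_starts=50, seed=rng.integers(2 ** 31))

    n_grid = int(round((t_max - t_min) / grid_step)) + 1
    grid = np.linspace(t_min, t_max, max(n_grid, 2))
    curves, areas, skipped = [], [], 0
    extra = [(point.a, point.b, point.t_ref, point.w)] if point.ok else []
    for _ in range(B):
        idx = rng.choice(T.size, size=T.size, replace=True)
        if np.unique(T[idx]).size < 4:
            skipped += 1
            continue
        refit = fit_tpc(T[idx], mu[idx], n_starts=n_starts,
                        seed=rng.integers(2 ** 31), extra_starts=extra)
        if not refit.ok:
            skipped += 1
            continue
        curves.append(refit(grid))
        areas.append(autpc(refit, t_min, t_max, grid_step))
    curves = np.array(curves)
    areas = np.array(areas)
    lower = np.percentile(curves, 2.5, axis=0)
    upper = np.percentile(curves, 97.5, axis=0)
    ai = (float(np.percentile(areas, 2.5)), float(np.percentile(areas, 97.5)))
    return TPCBootstrap(grid, lower, upper, ai, areas, len(areas), skipped)


def rising_part(temperatures, rates, fit: TPCFit, mode: str = "fitted"):
    """Observations on the rising limb of the TPC (μ > 0 and T ≤ T_opt).

    ``mode='fitted'`` uses the fitted T_opt; ``mode='empirical'`` uses the
    temperature with the largest mean observed rate.  When T_opt exceeds the
    warmest experimental temperature every positive-rate observation is
    retained (which the T ≤ T_opt mask already implies).
    """
    T = np.asarray(temperatures, dtype=float)
    mu = np.asarray(rates, dtype=float)
    if mode == "fitted":
        t_cut = tpc_topt(fit)
    elif mode == "empirical":
        levels = np.unique(T)
        means = np.array([mu[T == lev].mean() for lev in levels])
        t_cut = levels[int(np.argmax(means))]
    else:
        raise ValueError("mode must be 'fitted' or 'empirical'")
    keep = (mu > 0) & (T <= t_cut)
    return T[keep], mu[keep]


@dataclass
class ArrheniusFit:
    """OLS Arrhenius fit of ln(rate) on 1/(k*T_kelvin)."""

    ea: float          # activation energy, eV
    ln_a: float        # ln pre-exponential factor
    se_ea: float       # standard error of Ea, eV
    r2: float
    n: int
    k_boltzmann: float = field(default=K_BOLTZMANN, repr=False)


def fit_arrhenius(temperatures_c, rates) -> ArrheniusFit:
    """Estimate the activation energy from positive growth rates.

    Regresses ln(μ) on x = 1/(k*T_K) with T_K = T°C + 273.15 and returns
    Ea = −slope, so that rates rising with temperature give a positive Ea
    (the convention of R = A·exp(−Ea/kT)).
    """
    T = np.asarray(temperatures_c, dtype=float)
    mu = np.asarray(rates, dtype=float)
    if T.size < 3:
        raise ValueError("need at least 3 observations for an Arrhenius fit")
    if np.unique(T).size < 2:
        raise ValueError("need at least 2 distinct temperatures")
    if np.any(mu <= 0):
        raise ValueError("all rates must be positive; filter with rising_part")
    x = 1.0 / (K_BOLTZMANN * (T + 273.15))
    res = stats.linregress(x, np.log(mu))
    return ArrheniusFit(ea=-float(res.slope), ln_a=float(res.intercept),
                        se_ea=float(res.stderr), r2=float(res.rvalue ** 2),
                        n=int(T.size))


@dataclass
class EaSummary:
    """Across-phosphorus summary of a strain's activation energies."""

    strain: str
    mean_ea: float
    sd_ea: float
    t_stat: float
    p_value: float
    n: int
    reference: float = EA_REFERENCE


def ea_summary(eas, reference: float = EA_REFERENCE, strain: str = "") -> EaSummary:
    """Mean/SD of Ea values and a two-sided one-sample t-test vs ``reference``.

    With fewer than 2 values the summary is returned without a test
    (t and p are NaN).
    """
    eas = np.asarray(eas, dtype=float)
    if eas.size == 0:
        raise ValueError("no activation energies supplied")
    if eas.size < 2:
        return EaSummary(strain, float(eas[0]), float("nan"),
                         float("nan"), float("nan"), 1, reference)
    sd = float(eas.std(ddof=1))
    if sd == 0.0:
        # degenerate: identical values; t is 0 on the reference, else infinite
        if eas.mean() == reference:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(eas.mean() - reference)) * float("inf"), 0.0
    else:
        t, p = stats.ttest_1samp(eas, reference)
    return EaSummary(strain, float(eas.mean()), sd,
                     float(t), float(p), int(eas.size), reference)
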
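"""Two-stage test for temperature-dependent local adaptation.

Stage 1 regresses a strain trait (canonically the minimal phosphorus
requirement P*) on the phosphorus concentration of each strain's source
lake, separately for every experimental temperature, keeping each slope
and its standard error.  Stage 2 regresses those slopes on experimental
temperature by weighted least squares with inverse-variance weights
(1/SE²), so precisely estimated slopes dominate the trend.  A positive
stage-2 trend means strains from phosphorus-rich lakes raise their
phosphorus requirement faster under warming than strains from
phosphorus-poor lakes — the signature of temperature-dependent local
adaptation.  The machinery is generic over any trait / lake variable pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class SlopeEstimate:
    """Stage-1 trait-on-environment slope at one experimental temperature."""

    experimental_temperature: float
    slope: float
    se: float
    p_value: float
    n: int
    ok: bool = True


@dataclass
class SlopeTrend:
    """Stage-2 inverse-variance weighted trend of slopes on temperature."""

    trend_slope: float
    trend_se: float
    trend_p: float
    intercept: float
    weights: np.ndarray
    n: int


def trait_env_regression(env_values, trait_values,
                         experimental_temperature: float) -> SlopeEstimate:
    """OLS of a trait on a lake environmental variable across strains.

    Pairs with a missing trait or environment value are dropped (strains
    whose trait was excluded, or whose lake lacks chemistry data, simply do
    not enter this temperature's regression).  Fewer than 3 complete pairs
    yields an untestable estimate (``ok=False``).
    """
    x = np.asarray(env_values, dtype=float)
    y = np.asarray(trait_values, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        return SlopeEstimate(experimental_temperature, float("nan"),
                             float("nan"), float("nan"), int(x.size),
                             ok=False)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return SlopeEstimate(experimental_temperature,
                         float(model.params[1]), float(model.bse[1]),
                         float(model.pvalues[1]), int(x.size))


def slope_trend(slopes) -> SlopeTrend:
    """WLS of stage-1 slopes on experimental temperature, weights 1/SE²."""
    usable = [s for s in slopes if s.ok]
    if len(usable) < 3:
        raise ValueError("need at least 3 testable slope estimates")
    t = np.array([s.experimental_temperature for s in usable])
    b = np.array([s.slope for s in usable])
    se = np.array([s.se for s in usable])
    if np.any(se == 0) or not np.all(np.isfinite(se)):
        raise ValueError("slope standard errors must be finite and nonzero")
    w = 1.0 / se ** 2
    model = sm.WLS(b, sm.add_constant(t), weights=w).fit()
    return SlopeTrend(float(model.params[1]), float(model.bse[1]),
                      float(model.pvalues[1]), float(model.params[0]),
                      w, len(usable))


def two_stage(trait_table: pd.DataFrame, env: dict,
              trait_col: str = "p_star", strain_col: str = "strain",
              group_col: str = "temperature_C"):
    """Run both stages from a per-strain trait table.

    Parameters
    ----------
    trait_table : DataFrame
        One row per strain x experimental temperature with the trait column
        (rows whose trait is NaN are treated as excluded).
    env : mapping strain -> lake environmental value
        Strains absent from the mapping are dropped from every regression.

    Returns (list of SlopeEstimate, SlopeTrend).
    """
    estimates = []
    for temp, g in trait_table.groupby(group_col, sort=True):
        x = np.array([env.get(s, np.nan) for s in g[strain_col]])
        estimates.append(trait_env_regression(x, g[trait_col].to_numpy(),
                                              float(temp)))
    return estimates, slope_trend(estimates)


def slopes_to_frame(slopes) -> pd.DataFrame:
    return pd.DataFrame([{"temperature_C": s.experimental_temperature,
                          "slope": s.slope, "se": s.se, "p_value": s.p_value,
                          "n": s.n, "ok": s.ok} for s in slopes])
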
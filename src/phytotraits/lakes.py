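"""Growing-season lake temperature and phosphorus summaries.

Lake means are computed from monitoring records as a two-stage average:
per-year mean of the August–October measurements at 5 m depth, then an
unweighted mean across years (2018–2022 by default), so unevenly sampled
years carry equal weight.  For sparsely monitored lakes the temperature
series is densified with a seasonal regression — a linear year trend plus
one annual harmonic — and the seasonal mean is taken over six predicted
dates evenly spaced from Aug 1 to Oct 31.  Phosphorus is never modeled
(it shows no seasonal cycle); only direct means are used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROWING_SEASON_MONTHS = (8, 9, 10)
DEFAULT_YEARS = tuple(range(2018, 2023))
DEFAULT_DEPTH_M = 5.0


class LakeDataError(ValueError):
    """Raised when a lake has no usable records in the requested window."""


def decimal_year(dates) -> np.ndarray:
    """Dates as decimal years (year + elapsed fraction of that year)."""
    dates = pd.DatetimeIndex(dates)
    start = pd.to_datetime(dates.year.astype(str) + "-01-01")
    end = pd.to_datetime((dates.year + 1).astype(str) + "-01-01")
    frac = (dates - start).total_seconds() / (end - start).total_seconds()
    return dates.year.to_numpy() + np.asarray(frac)


@dataclass
class LakeEnvironment:
    """Growing-season means for one lake."""

    lake: str
    mean_temperature: float
    mean_phosphorus: float
    temperature_method: str   # 'direct' or 'modeled'
    years_used: tuple
    n_records: int


@dataclass
class SeasonalModel:
    """Temperature = intercept + year trend + one annual harmonic."""

    intercept: float
    year_slope: float     # °C per year
    sin_coef: float
    cos_coef: float
    residual_sd: float
    ref_year: float       # year subtracted before the trend term

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.sin_coef, self.cos_coef))

    def predict(self, dates) -> np.ndarray:
        dy = decimal_year(pd.DatetimeIndex(pd.to_datetime(dates)))
        dayfrac = dy - np.floor(dy)
        return (self.intercept + self.year_slope * (dy - self.ref_year)
                + self.sin_coef * np.sin(2 * np.pi * dayfrac)
                + self.cos_coef * np.cos(2 * np.pi * dayfrac))


def _window_records(records, lake, variable, months, years, depth_m,
                    depth_tol):
    df = records[(records["lake"] == lake)
                 & (records["variable"] == variable)].copy()
    df["date"] = pd.to_datetime(df["date"])
    depth = df["depth_m"].astype(float)
    # integrated-depth samples (recorded as NaN) pass through the filter
    df = df[depth.isna() | ((depth - depth_m).abs() <= depth_tol)]
    df = df[df["date"].dt.month.isin(months) & df["date"].dt.year.isin(years)]
    return df


def season_mean(records, lake, variable="temperature",
                months=GROWING_SEASON_MONTHS, years=DEFAULT_YEARS,
                depth_m=DEFAULT_DEPTH_M, depth_tol=1.0):
    """Two-stage growing-season mean: within-year, then across years.

    Returns (mean, years_used, n_records).  Raises LakeDataError if no
    in-window records exist for the lake.
    """
    df = _window_records(records, lake, variable, months, years,
                         depth_m, depth_tol)
    if df.empty:
        raise LakeDataError(
            f"no {variable} records for lake {lake!r} in the requested "
            f"window (months {tuple(months)}, years {tuple(years)})")
    per_year = df.groupby(df["date"].dt.year)["value"].mean()
    return (float(per_year.mean()), tuple(int(y) for y in per_year.index),
            int(len(df)))


def fit_seasonal_model(records, lake=None) -> SeasonalModel:
    """OLS of temperature on (year, sin 2π·dayfrac, cos 2π·dayfrac).

    ``records`` may be pre-filtered to one lake or ``lake`` can be given.
    Requires ≥ 8 records spanning ≥ 2 calendar years.
    """
    df = records
    if lake is not None:
        df = df[df["lake"] == lake]
    df = df[df["variable"] == "temperature"]
    dates = pd.DatetimeIndex(pd.to_datetime(df["date"]))
    y = df["value"].to_numpy(dtype=float)
    if y.size < 8:
        raise ValueError("need at least 8 records to fit a seasonal model")
    if np.unique(dates.year).size < 2:
        raise ValueError("records must span at least 2 years")
    dy = decimal_year(dates)
    ref_year = float(np.floor(dy.min()))
    dayfrac = dy - np.floor(dy)
    X = np.column_stack([np.ones_like(dy), dy - ref_year,
                         np.sin(2 * np.pi * dayfrac),
                         np.cos(2 * np.pi * dayfrac)])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("design is rank deficient (records cover too "
                         "few distinct days of year)")
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(y.size - 4, 1)
    return SeasonalModel(float(beta[0]), float(beta[1]), float(beta[2]),
                         float(beta[3]), float(np.sqrt(resid @ resid / dof)),
                         ref_year)


def season_prediction_dates(year: int) -> pd.DatetimeIndex:
    """Six dates evenly distributed over August–October of one year.

    The dates sit at the midpoints of six equal subintervals of
    [Aug 1, Nov 1), so their average is quadrature-accurate for a smooth
    seasonal curve (an endpoints-inclusive grid overweights the window
    edges and misses the dense seasonal mean by ~0.15 °C at a typical 6 °C
    annual amplitude).
    """
    start = pd.Timestamp(f"{year}-08-01")
    span = pd.Timestamp(f"{year}-11-01") - start
    return pd.DatetimeIndex([start + (k + 0.5) / 6 * span for k in range(6)])


def predict_season_mean(model: SeasonalModel, years=DEFAULT_YEARS) -> float:
    """Across-year mean of six predicted points in Aug–Oct of each year."""
    yearly = [float(model.predict(season_prediction_dates(year)).mean())
              for year in years]
    return float(np.mean(yearly))


def summarize_lake(records, lake, months=GROWING_SEASON_MONTHS,
                   years=DEFAULT_YEARS, depth_m=DEFAULT_DEPTH_M,
                   depth_tol=1.0, temperature_method="auto",
                   sparse_threshold=2.0) -> LakeEnvironment:
    """Growing-season temperature and phosphorus summary for one lake.

    ``temperature_method``: 'direct' (two-stage mean of raw records),
    'modeled' (seasonal-regression prediction), or 'auto', which models the
    lake when it averages fewer than ``sparse_threshold`` in-window
    temperature records per year.
    """
    t_mean, t_years, t_n = season_mean(records, lake, "temperature", months,
                                       years, depth_m, depth_tol)
    method = temperature_method
    if method == "auto":
        method = "modeled" if t_n / max(len(t_years), 1) < sparse_threshold \
            else "direct"
    if method == "modeled":
        lake_temp = records[(records["lake"] == lake)
                            & (records["variable"] == "temperature")]
        model = fit_seasonal_model(lake_temp)
        t_mean = predict_season_mean(model, years=t_years)
    elif method != "direct":
        raise ValueError("temperature_method must be auto/direct/modeled")
    p_mean, p_years, p_n = season_mean(records, lake, "total_phosphorus",
                                       months, years, depth_m, depth_tol)
    return LakeEnvironment(lake, t_mean, p_mean, method,
                           t_years, t_n + p_n)
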
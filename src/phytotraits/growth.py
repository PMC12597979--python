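"""Per-well exponential growth rates from fluorescence time series.

Each well's ln(RFU) trajectory is fit with four candidate shapes that
differ only in whether a lag and/or a saturation phase flanks the
exponential segment:

  exponential      one line through all points
  lag              flat level, then a line
  saturation       a line, then a flat level
  lag_saturation   flat level, line, flat level

Each model partitions the observed timepoints into segments (at least two
points per segment, so flat levels and slopes are genuinely estimated);
within a partition the least-squares solution is exact (segment means and
a segment OLS line), and the partition itself is found by enumerating the
observed time grid.  μ — the OLS slope of the line-segment points — is
therefore estimated the same way in every model and is the only quantity
carried downstream; negative μ is allowed.  Reported lag/saturation times
are where the fitted line meets the flat level(s), which is invariant to
which of two tied partitions the scan lands on when a point sits exactly
on both segments.  The best model per well is chosen by AICc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

MODEL_NPARAMS = {"exponential": 2, "lag": 3, "saturation": 3,
                 "lag_saturation": 4}


@dataclass
class FluorescenceSeries:
    """One well's time series of relative fluorescence units."""

    strain: str
    temperature: float
    phosphorus: float
    replicate: int
    times: np.ndarray
    rfu: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if self.times.shape != self.rfu.shape:
            raise ValueError("times and rfu must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.rfu)):
            raise ValueError("rfu values must be finite")

    def __len__(self):
        return self.times.size


@dataclass
class GrowthFit:
    """One candidate growth model fit to a single well."""

    model: str
    mu: float                 # day⁻¹, slope of the ln-RFU line segment
    intercept: float          # fitted ln RFU at t = 0
    lag_time: float | None
    sat_time: float | None
    rss: float
    aicc: float
    n_points: int

    @property
    def n_params(self) -> int:
        return MODEL_NPARAMS[self.model]


class TooFewPointsError(ValueError):
    """Raised when a well has too few usable points to estimate a rate."""


def compute_detection_limit(blank_rfu) -> float:
    """Detection limit: half of the median blank-media fluorescence."""
    blanks = np.asarray(blank_rfu, dtype=float)
    if blanks.size == 0:
        raise ValueError("no blank readings supplied")
    return float(np.median(blanks)) / 2.0


def filter_series(series: FluorescenceSeries, threshold: float) -> FluorescenceSeries:
    """Drop readings strictly below the detection threshold.

    Metadata and point order are preserved; the result may be empty.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    keep = series.rfu >= threshold
    return replace(series, times=series.times[keep], rfu=series.rfu[keep])


def aicc(rss: float, n: int, p: int) -> float:
    """Small-sample corrected AIC for a Gaussian least-squares fit.

    Uses the constant-dropped form AICc = n·ln(rss/n) + 2p + 2p(p+1)/(n−p−1);
    only differences between models fitted to the same data matter.  ``p``
    counts the mean-model parameters (breakpoints included), not the error
    variance.  rss is floored at a tiny positive value so that numerically
    perfect fits stay comparable.
    """
    if n <= p + 1:
        raise ValueError("AICc undefined for n <= p + 1")
    rss = max(float(rss), 1e-300)
    return n * math.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


class _Segments:
    """Prefix-sum helper for exact segment fits on a fixed (t, y) series.

    Segment bounds are half-open index ranges [lo, hi).  ``flat`` returns
    the RSS of a constant fit; ``line`` the (rss, intercept, slope) of a
    segment OLS line.
    """

    def __init__(self, t: np.ndarray, y: np.ndarray):
        z = np.zeros(1)
        self.t1 = np.concatenate([z, np.cumsum(t)])
        self.t2 = np.concatenate([z, np.cumsum(t * t)])
        self.y1 = np.concatenate([z, np.cumsum(y)])
        self.y2 = np.concatenate([z, np.cumsum(y * y)])
        self.ty = np.concatenate([z, np.cumsum(t * y)])

    def _sums(self, lo, hi):
        k = hi - lo
        return (k, self.t1[hi] - self.t1[lo], self.t2[hi] - self.t2[lo],
                self.y1[hi] - self.y1[lo], self.y2[hi] - self.y2[lo],
                self.ty[hi] - self.ty[lo])

    def flat(self, lo, hi):
        k, _, _, sy, sy2, _ = self._sums(lo, hi)
        rss = sy2 - sy * sy / k
        return np.maximum(rss, 0.0), sy / k

    def line(self, lo, hi):
        k, st, st2, sy, sy2, sty = self._sums(lo, hi)
        sxx = st2 - st * st / k
        sxy = sty - st * sy / k
        slope = sxy / sxx
        rss = np.maximum((sy2 - sy * sy / k) - slope * sxy, 0.0)
        return rss, (sy - slope * st) / k, slope


def _crossing(level, intercept, slope, fallback):
    """Time where the line meets a flat level (the breakpoint estimate)."""
    if slope == 0:
        return float(fallback)
    return float((level - intercept) / slope)


def fit_growth_models(series: FluorescenceSeries) -> list[GrowthFit]:
    """Fit every estimable candidate model to one well's ln(RFU) series.

    A model is included only when the series has enough points both to
    identify its parameters and to give a finite AICc (n ≥ p + 2), except
    the plain exponential, which is always fit for n ≥ 3 (with AICc = +inf
    at n = 3 so that it can still be selected as the only candidate).
    Segment partitions are enumerated on the observed time grid with ≥ 2
    points per segment; each partition's fit is exact least squares.
    """
    t = series.times
    n = t.size
    if n < 3:
        raise TooFewPointsError(
            f"well {series.strain}/{series.temperature}C/"
            f"{series.phosphorus}/{series.replicate}: {n} usable points")
    if np.any(series.rfu <= 0):
        raise ValueError("non-positive RFU reached the log; filter first")
    y = np.log(series.rfu)
    seg = _Segments(t, y)
    fits: list[GrowthFit] = []

    # (i) single line through everything
    rss, c, slope = seg.line(0, n)
    a = aicc(rss, n, 2) if n >= 4 else float("inf")
    fits.append(GrowthFit("exponential", float(slope), float(c),
                          None, None, float(rss), a, n))

    # (ii) flat on points [0..i], line on [i+1..n-1]
    if n >= 5:
        i = np.arange(1, n - 2)
        rss_f, level = seg.flat(0, i + 1)
        rss_l, c, slope = seg.line(i + 1, n)
        rss = rss_f + rss_l
        k = int(np.argmin(rss))
        lag = _crossing(level[k], c[k], slope[k], t[i[k]])
        fits.append(GrowthFit("lag", float(slope[k]), float(c[k]),
                              lag, None, float(rss[k]), aicc(rss[k], n, 3),
                              n))

    # (iii) line on [0..j], flat on [j+1..n-1]
    if n >= 5:
        j = np.arange(1, n - 2)
        rss_l, c, slope = seg.line(0, j + 1)
        rss_f, level = seg.flat(j + 1, n)
        rss = rss_l + rss_f
        k = int(np.argmin(rss))
        sat = _crossing(level[k], c[k], slope[k], t[j[k]])
        fits.append(GrowthFit("saturation", float(slope[k]), float(c[k]),
                              None, sat, float(rss[k]), aicc(rss[k], n, 3),
                              n))

    # (iv) flat [0..i], line [i+1..j], flat [j+1..n-1], j >= i + 2
    if n >= 6:
        ii, jj = np.meshgrid(np.arange(1, n - 4), np.arange(3, n - 2),
                             indexing="ij")
        keep = jj >= ii + 2
        ii, jj = ii[keep], jj[keep]
        rss_lo, level_lo = seg.flat(0, ii + 1)
        rss_l, c, slope = seg.line(ii + 1, jj + 1)
        rss_hi, level_hi = seg.flat(jj + 1, n)
        rss = rss_lo + rss_l + rss_hi
        k = int(np.argmin(rss))
        lag = _crossing(level_lo[k], c[k], slope[k], t[ii[k]])
        sat = _crossing(level_hi[k], c[k], slope[k], t[jj[k]])
        fits.append(GrowthFit("lag_saturation", float(slope[k]), float(c[k]),
                              lag, sat, float(rss[k]), aicc(rss[k], n, 4),
                              n))
    return fits


def select_best(fits: list[GrowthFit]) -> GrowthFit:
    """Model with the lowest AICc; ties go to the fewer-parameter model."""
    if not fits:
        raise ValueError("no fits to select from")
    return min(fits, key=lambda f: (f.aicc, f.n_params))


def iter_series(df: pd.DataFrame):
    """Yield a FluorescenceSeries per well from a long-format table.

    Expects columns strain, temperature_C, phosphorus_umol_L, replicate,
    time_days, rfu (the schema written by the synthetic-data generator and
    expected of real plate-reader exports).
    """
    keys = ["strain", "temperature_C", "phosphorus_umol_L", "replicate"]
    df = df.sort_values(keys + ["time_days"], kind="mergesort")
    times = df["time_days"].to_numpy(dtype=float)
    rfu = df["rfu"].to_numpy(dtype=float)
    grouped = df.groupby(keys, sort=False)
    for (strain, temp, phos, rep), idx in grouped.indices.items():
        idx = np.sort(idx)
        yield FluorescenceSeries(str(strain), float(temp), float(phos),
                                 int(rep), times[idx], rfu[idx])


def fit_growth_table(df: pd.DataFrame, threshold: float,
                     min_points: int = 3) -> pd.DataFrame:
    """Detection-filter and fit every well of a long-format RFU table.

    Returns one row per estimable well: strain, temperature_C,
    phosphorus_umol_L, replicate, mu_per_day, model, aicc, n_points.
    Wells with fewer than ``min_points`` readings above the threshold are
    excluded (count them by comparing against the number of input wells).
    """
    rows = []
    for series in iter_series(df):
        kept = filter_series(series, threshold)
        if len(kept) < min_points:
            continue
        best = select_best(fit_growth_models(kept))
        rows.append({"strain": series.strain,
                     "temperature_C": series.temperature,
                     "phosphorus_umol_L": series.phosphorus,
                     "replicate": series.replicate,
                     "mu_per_day": best.mu,
                     "model": best.model,
                     "aicc": best.aicc,
                     "n_points": best.n_points})
    return pd.DataFrame(rows)
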
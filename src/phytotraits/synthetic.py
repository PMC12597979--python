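"""Synthetic factorial growth experiments and lake monitoring records.

The generator emulates a plate-reader growth experiment crossing eight
diatom strains with six temperatures and six phosphorus levels (four
replicate wells each), plus the sparse seasonal monitoring series of the
strains' source lakes.  Every strain carries a known ground-truth growth
surface

    R(T, S) = μ_max(T) · S / (K_s(T) + S)

with μ_max(T) the Thomas-2012 thermal performance curve and K_s(T) a
quadratic in temperature with a strain-specific minimum — the shape that
produces the U-shaped P*(T) expectation.  The quadratic coefficient
(``ks_temp_sensitivity``) increases with the phosphorus concentration of a
strain's source lake in proportion to ``adaptation_strength``, which plants
a detectable temperature-dependent local-adaptation signal; at strength 0
the sensitivity is identical across strains and the planted signal is null.

All randomness flows through explicit integer seeds, so identical inputs
reproduce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .monod import monod
from .thermal import thomas_tpc

# Factorial design of the emulated experiment: 6 temperatures x 6
# orthophosphate-P levels, 4 replicates, 11 measurements over 6 days
# (twice daily for 4 days, then daily), initial density 10 RFU.
DEFAULT_TEMPERATURES = (12.0, 16.0, 20.0, 22.0, 24.0, 26.0)
DEFAULT_PHOSPHORUS = (1.94, 3.87, 7.75, 15.50, 31.00, 47.47)
DEFAULT_TIMEPOINTS = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0)

#: quadratic K_s(T) curvature added per μg·L⁻¹ of source-lake phosphorus at
#: adaptation_strength 1 (μmol·L⁻¹·°C⁻² per μg·L⁻¹)
SENSITIVITY_PER_LAKE_P = 0.003
#: baseline K_s(T) curvature common to all strains (μmol·L⁻¹·°C⁻²)
BASELINE_KS_CURVATURE = 0.002

SERIES_SCHEMA = "# phytotraits schema=fluorescence_series v1"
LAKE_SCHEMA = "# phytotraits schema=lake_monitoring v1"


@dataclass(frozen=True)
class StrainTruth:
    """Ground-truth growth surface and provenance of one synthetic strain."""

    strain_id: str
    a: float                      # day⁻¹ TPC scale
    b: float                      # °C⁻¹ TPC exponential scale
    t_ref: float                  # °C, centre of the TPC quadratic factor
    w: float                      # °C, thermal niche width
    ks_base: float                # μmol·L⁻¹, minimal half-saturation constant
    ks_temp_sensitivity: float    # μmol·L⁻¹·°C⁻², K_s(T) curvature
    ks_t_min: float               # °C at which K_s(T) is minimal
    lag_mean: float               # days, mean of per-well exponential lag
    source_lake_phosphorus: float  # μg·L⁻¹ total P of the lake of origin

    def __post_init__(self):
        if self.w <= 0 or self.a <= 0 or self.ks_base <= 0:
            raise ValueError("w, a and ks_base must be positive")
        if self.lag_mean < 0:
            raise ValueError("lag_mean must be non-negative")

    def mu_max(self, T):
        return thomas_tpc(T, self.a, self.b, self.t_ref, self.w)

    def ks(self, T):
        T = np.asarray(T, dtype=float)
        return self.ks_base + self.ks_temp_sensitivity * (T - self.ks_t_min) ** 2

    def growth_rate(self, T, S):
        """True growth rate surface R(T, S); non-decreasing in S."""
        return monod(S, self.mu_max(T), self.ks(T))


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial design and observation model of a synthetic experiment."""

    temperature_levels: tuple = DEFAULT_TEMPERATURES
    phosphorus_levels: tuple = DEFAULT_PHOSPHORUS
    replicates: int = 4
    timepoints: tuple = DEFAULT_TIMEPOINTS
    initial_rfu: float = 10.0
    detection_floor: float = 2.25    # RFU below which readings are unreliable
    noise_cv: float = 0.10           # CV of multiplicative lognormal noise
    carrying_capacity: float | None = 500.0   # RFU; None = pure exponential
    blank_median_rfu: float = 4.5    # blank-media fluorescence level

    def __post_init__(self):
        for name in ("temperature_levels", "phosphorus_levels", "timepoints"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.size and np.any(np.diff(vals) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.initial_rfu <= 0:
            raise ValueError("initial_rfu must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")

    @property
    def n_wells_per_strain(self) -> int:
        return (len(self.temperature_levels) * len(self.phosphorus_levels)
                * self.replicates)


def make_truth(n_strains: int, adaptation_strength: float, seed: int,
               lake_p_range=(5.0, 60.0)) -> list[StrainTruth]:
    """Draw ground-truth parameters for ``n_strains`` synthetic strains.

    Source-lake phosphorus is drawn uniformly over ``lake_p_range`` (μg·L⁻¹,
    the range of Swiss peri-alpine lakes from oligotrophic to eutrophic) and

        ks_temp_sensitivity = BASELINE + adaptation_strength
                              * SENSITIVITY_PER_LAKE_P * lake_p

    so the sensitivity is a deterministic increasing function of lake
    phosphorus, identical across strains at strength 0.
    """
    if n_strains < 2:
        raise ValueError("need at least 2 strains (stage-1 regressions "
                         "require multiple source lakes)")
    rng = np.random.default_rng(seed)
    lake_p = rng.uniform(*lake_p_range, n_strains)
    truths = []
    for i in range(n_strains):
        truths.append(StrainTruth(
            strain_id=f"S{i + 1:02d}",
            a=rng.uniform(0.15, 0.30),
            b=rng.uniform(0.04, 0.08),
            t_ref=rng.uniform(16.0, 22.0),
            w=rng.uniform(28.0, 40.0),
            ks_base=rng.uniform(0.5, 2.5),
            ks_temp_sensitivity=(BASELINE_KS_CURVATURE
                                 + adaptation_strength
                                 * SENSITIVITY_PER_LAKE_P * lake_p[i]),
            ks_t_min=rng.uniform(14.0, 17.0),
            lag_mean=rng.uniform(0.1, 0.4),
            source_lake_phosphorus=float(lake_p[i]),
        ))
    return truths


def _latent_trajectory(times, n0, rate, lag, capacity):
    """Density: flat at n0 until the lag, then (logistic-capped) exponential."""
    dt = np.maximum(times - lag, 0.0)
    if capacity is None:
        return n0 * np.exp(rate * dt)
    growth = np.exp(rate * dt)
    return capacity * n0 * growth / (capacity + n0 * (growth - 1.0))


def simulate_series(truth: StrainTruth, design: ExperimentDesign,
                    seed: int) -> pd.DataFrame:
    """Simulate every well of one strain; long-format fluorescence table.

    Per well a lag is drawn from Exponential(lag_mean), the latent density
    grows at the true rate R(T, S) (optionally saturating at the design's
    carrying capacity) and observed RFU is latent density times mean-one
    multiplicative lognormal noise with the design's CV.  Readings below
    the detection floor are emitted unchanged — filtering is the analysis
    pipeline's job, not the instrument's.
    """
    if design.noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    times = np.asarray(design.timepoints, dtype=float)
    sigma = np.sqrt(np.log1p(design.noise_cv ** 2))
    rows = []
    for temp in design.temperature_levels:
        for phos in design.phosphorus_levels:
            rate = float(truth.growth_rate(temp, phos))
            for rep in range(1, design.replicates + 1):
                lag = (rng.exponential(truth.lag_mean)
                       if truth.lag_mean > 0 else 0.0)
                latent = _latent_trajectory(times, design.initial_rfu, rate,
                                            lag, design.carrying_capacity)
                if sigma > 0:
                    noise = np.exp(rng.normal(-0.5 * sigma ** 2, sigma,
                                              times.size))
                else:
                    noise = 1.0
                rfu = latent * noise
                for t, v in zip(times, rfu):
                    rows.append((truth.strain_id, temp, phos, rep, t, v))
    return pd.DataFrame(rows, columns=["strain", "temperature_C",
                                       "phosphorus_umol_L", "replicate",
                                       "time_days", "rfu"])


def simulate_experiment(truths, design: ExperimentDesign,
                        seed: int) -> pd.DataFrame:
    """Simulate all strains; per-strain child seeds from one SeedSequence."""
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(len(truths))
    return pd.concat([simulate_series(truth, design, child)
                      for truth, child in zip(truths, children)],
                     ignore_index=True)


def simulate_blanks(design: ExperimentDesign, seed: int,
                    n_per_level: int = 8) -> np.ndarray:
    """Blank-media fluorescence readings across the phosphorus levels.

    Lognormal around the design's blank level with 5% CV, so the half-median
    detection limit lands near ``blank_median_rfu / 2``.
    """
    rng = np.random.default_rng(seed)
    n = n_per_level * len(design.phosphorus_levels)
    sigma = np.sqrt(np.log1p(0.05 ** 2))
    return design.blank_median_rfu * np.exp(rng.normal(0.0, sigma, n))


def simulate_lake_monitoring(trend: float, amplitude: float, phase: float,
                             mean: float, sampling_dates, noise_sd: float,
                             seed: int, lake: str = "lake",
                             depth_m: float = 5.0,
                             variable: str = "temperature",
                             ref_year: float | None = None) -> pd.DataFrame:
    """Seasonal monitoring records: trend + annual sinusoid + noise.

    value(date) = mean + trend·(decimal_year − ref_year)
                  + amplitude·sin(2π·dayfrac + phase) + N(0, noise_sd²)
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    dates = pd.DatetimeIndex(pd.to_datetime(list(sampling_dates)))
    if dates.size == 0:
        raise ValueError("sampling_dates must be nonempty")
    from .lakes import decimal_year
    dy = decimal_year(dates)
    if ref_year is None:
        ref_year = float(np.floor(dy.min()))
    dayfrac = dy - np.floor(dy)
    rng = np.random.default_rng(seed)
    values = (mean + trend * (dy - ref_year)
              + amplitude * np.sin(2 * np.pi * dayfrac + phase)
              + (rng.normal(0.0, noise_sd, dates.size) if noise_sd > 0
                 else 0.0))
    return pd.DataFrame({"lake": lake,
                         "date": dates.strftime("%Y-%m-%d"),
                         "depth_m": depth_m,
                         "variable": variable,
                         "value": values})


def make_lake_records(truths, seed: int,
                      years=range(2018, 2023)) -> pd.DataFrame:
    """Monthly monitoring records for every strain's source lake.

    Lake temperature means increase mildly with lake phosphorus (the
    positive temperature–phosphorus correlation seen across peri-alpine
    lakes); total phosphorus records scatter around each strain's true
    source-lake concentration with no seasonal cycle.
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(2 * len(truths))
    dates = [f"{y}-{m:02d}-15" for y in years for m in range(1, 13)]
    frames = []
    for i, truth in enumerate(truths):
        lake = f"lake_{truth.strain_id}"
        temp_mean = 10.0 + 0.08 * truth.source_lake_phosphorus
        frames.append(simulate_lake_monitoring(
            trend=0.03, amplitude=6.0, phase=-2.0, mean=temp_mean,
            sampling_dates=dates, noise_sd=0.5, seed=children[2 * i],
            lake=lake, variable="temperature"))
        frames.append(simulate_lake_monitoring(
            trend=0.0, amplitude=0.0, phase=0.0,
            mean=truth.source_lake_phosphorus, sampling_dates=dates,
            noise_sd=0.02 * truth.source_lake_phosphorus,
            seed=children[2 * i + 1], lake=lake, variable="total_phosphorus"))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------- file I/O

def write_series_csv(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(SERIES_SCHEMA + "\n")
        df.to_csv(fh, index=False)


def read_series_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_lake_csv(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(LAKE_SCHEMA + "\n")
        df.to_csv(fh, index=False)


def read_lake_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def truths_to_json(truths, path=None) -> str:
    payload = json.dumps([dataclasses.asdict(t) for t in truths], indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(payload)
    return payload


def truths_from_json(source) -> list[StrainTruth]:
    """Rebuild truths from a JSON string or file path."""
    text = source
    try:
        items = json.loads(text)
    except (json.JSONDecodeError, TypeError):
        with open(source) as fh:
            items = json.load(fh)
    return [StrainTruth(**item) for item in items]
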
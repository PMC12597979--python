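"""End-to-end orchestration of the trait-estimation pipeline.

Stages run in a fixed order — growth rates from raw fluorescence, then
thermal (TPC / AUTPC / Arrhenius) and resource (Monod / P*) traits, trait
response smooths, lake environment summaries and the two-stage local
adaptation analysis — with every intermediate table written out and a run
manifest recording seeds, versions and record counts.  A single master
seed is expanded into independent per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``, so any stage can be reproduced
in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import phytotraits.adaptation as adapt
import phytotraits.growth as growth_mod
import phytotraits.lakes as lakes_mod
import phytotraits.smooth as smooth_mod
import phytotraits.synthetic as synth
import phytotraits.thermal as thermal_mod
from .monod import DEFAULT_MORTALITY, bootstrap_monod, fit_monod, validate_monod

log = logging.getLogger("phytotraits")

STAGE_NAMES = ("simulate", "blanks", "lakes", "tpc", "monod", "bootstrap")


@dataclass
class PipelineConfig:
    # synthetic-experiment inputs (used when no CSV paths are given)
    n_strains: int = 8
    adaptation_strength: float = 1.0
    seed: int = 0
    design: synth.ExperimentDesign = field(
        default_factory=synth.ExperimentDesign)
    # analysis knobs
    mortality: float = DEFAULT_MORTALITY
    detection_threshold: float | None = None   # None: from blank readings
    tpc_n_starts: int = 250
    monod_n_starts: int = 30
    bootstrap_B: int = 1000
    do_bootstrap: bool = False
    ea_reference: float = thermal_mod.EA_REFERENCE
    edf_threshold: float = 1.5
    autpc_range: tuple = (12.0, 26.0)
    # optional external inputs / outputs
    series_csv: str | None = None
    blank_csv: str | None = None
    lake_csv: str | None = None
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["autpc_range"] = list(self.autpc_range)
        for key in ("temperature_levels", "phosphorus_levels", "timepoints"):
            d["design"][key] = list(d["design"][key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "design" in d and not isinstance(d["design"],
                                            synth.ExperimentDesign):
            dd = dict(d["design"])
            for key in ("temperature_levels", "phosphorus_levels",
                        "timepoints"):
                if key in dd:
                    dd[key] = tuple(dd[key])
            d["design"] = synth.ExperimentDesign(**dd)
        if "autpc_range" in d:
            d["autpc_range"] = tuple(d["autpc_range"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def stage_seeds(seed: int) -> dict:
    """Expand the master seed into named per-stage SeedSequences."""
    children = np.random.SeedSequence(seed).spawn(len(STAGE_NAMES))
    return dict(zip(STAGE_NAMES, children))


# -------------------------------------------------------------- stage runs

def thermal_stage(growth_df: pd.DataFrame, n_starts: int, seed,
                  autpc_range=(12.0, 26.0), ea_reference=0.32,
                  bootstrap_B: int | None = None):
    """Per strain x phosphorus TPC traits and per-strain Ea summaries."""
    rng = np.random.default_rng(seed)
    tpc_rows, ea_rows = [], []
    for (strain, phos), g in growth_df.groupby(
            ["strain", "phosphorus_umol_L"], sort=True):
        T = g["temperature_C"].to_numpy(dtype=float)
        mu = g["mu_per_day"].to_numpy(dtype=float)
        row = {"strain": strain, "phosphorus_umol_L": phos, "n": len(g)}
        if np.unique(T).size < 4:
            tpc_rows.append({**row, "ok": False})
            continue
        fit = thermal_mod.fit_tpc(T, mu, n_starts=n_starts,
                                  seed=rng.integers(2 ** 31))
        row.update(ok=fit.ok, a=fit.a, b=fit.b, t_ref=fit.t_ref, w=fit.w,
                   rss=fit.rss)
        if fit.ok:
            row["t_opt"] = thermal_mod.tpc_topt(fit)
            row["autpc"] = thermal_mod.autpc(fit, *autpc_range)
            if bootstrap_B:
                band = thermal_mod.bootstrap_tpc(
                    T, mu, B=bootstrap_B, seed=rng.integers(2 ** 31))
                row["autpc_lo"], row["autpc_hi"] = band.autpc_interval
            t_r, mu_r = thermal_mod.rising_part(T, mu, fit)
            if t_r.size >= 3 and np.unique(t_r).size >= 3:
                arr = thermal_mod.fit_arrhenius(t_r, mu_r)
                ea_rows.append({"strain": strain, "phosphorus_umol_L": phos,
                                "ea_ev": arr.ea, "se_ea": arr.se_ea,
                                "r2": arr.r2, "n": arr.n})
        tpc_rows.append(row)
    tpc_df = pd.DataFrame(tpc_rows)
    ea_df = pd.DataFrame(ea_rows)
    summaries = []
    if not ea_df.empty:
        for strain, g in ea_df.groupby("strain", sort=True):
            if len(g) < 2:
                continue
            s = thermal_mod.ea_summary(g["ea_ev"].to_numpy(),
                                       reference=ea_reference, strain=strain)
            summaries.append(dataclasses.asdict(s))
    return tpc_df, ea_df, pd.DataFrame(summaries)


def monod_stage(growth_df: pd.DataFrame, m: float, n_starts: int, seed,
                bootstrap_B: int | None = None) -> pd.DataFrame:
    """Per strain x temperature Monod fits with validity screening.

    The ``p_star`` column is NaN for excluded fits (negative K_s or P*,
    μ_max ≤ m, or a boundary hit); ``mu_max`` is kept whenever estimable.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (strain, temp), g in growth_df.groupby(
            ["strain", "temperature_C"], sort=True):
        S = g["phosphorus_umol_L"].to_numpy(dtype=float)
        mu = g["mu_per_day"].to_numpy(dtype=float)
        row = {"strain": strain, "temperature_C": temp, "n": len(g)}
        if np.unique(S).size < 3:
            rows.append({**row, "ok": False, "retained": False})
            continue
        fit = fit_monod(S, mu, n_starts=n_starts,
                                  seed=rng.integers(2 ** 31), m=m)
        record = validate_monod(fit)
        row.update(ok=fit.ok, mu_max=fit.mu_max if fit.ok else np.nan,
                   ks=fit.ks, p_star_raw=fit.p_star, rss=fit.rss,
                   retained=record.retained,
                   exclusion="|".join(record.reasons),
                   p_star=fit.p_star if record.retained else np.nan,
                   ks_valid=fit.ks if record.retained else np.nan)
        if bootstrap_B and fit.ok:
            boot = bootstrap_monod(S, mu, B=bootstrap_B,
                                             seed=rng.integers(2 ** 31), m=m)
            row.update(mu_max_lo=boot.ci_mu_max[0], mu_max_hi=boot.ci_mu_max[1],
                       ks_lo=boot.ci_ks[0], ks_hi=boot.ci_ks[1],
                       p_star_lo=boot.ci_p_star[0],
                       p_star_hi=boot.ci_p_star[1],
                       p_star_boot_mean=boot.mean_p_star)
        rows.append(row)
    return pd.DataFrame(rows)


def smooth_stage(tpc_df, ea_df, monod_df, k: int = 3,
                 edf_threshold: float = 1.5) -> pd.DataFrame:
    """Trait-response smooths: resource traits vs T, thermal traits vs P."""
    pieces = []
    if not monod_df.empty:
        for trait in ("p_star", "ks_valid", "mu_max"):
            if trait in monod_df:
                pieces.append(smooth_mod.trait_smooth_table(
                    monod_df, trait, "temperature_C", k=k))
    if not tpc_df.empty and "autpc" in tpc_df:
        pieces.append(smooth_mod.trait_smooth_table(
            tpc_df, "autpc", "phosphorus_umol_L", k=k))
    if not ea_df.empty:
        pieces.append(smooth_mod.trait_smooth_table(
            ea_df, "ea_ev", "phosphorus_umol_L", k=k))
    return pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame()


def lake_stage(lake_records: pd.DataFrame, lakes=None) -> pd.DataFrame:
    """Summaries for every lake; lakes without chemistry stay NaN."""
    if lakes is None:
        lakes = sorted(lake_records["lake"].unique())
    rows = []
    for lake in lakes:
        try:
            env = lakes_mod.summarize_lake(lake_records, lake)
            rows.append({"lake": lake,
                         "mean_temperature": env.mean_temperature,
                         "mean_phosphorus": env.mean_phosphorus,
                         "temperature_method": env.temperature_method})
        except lakes_mod.LakeDataError as exc:
            log.warning("lake %s dropped from environment summaries: %s",
                        lake, exc)
            rows.append({"lake": lake, "mean_temperature": np.nan,
                         "mean_phosphorus": np.nan,
                         "temperature_method": "missing"})
    return pd.DataFrame(rows)


# ------------------------------------------------------------- full runs

@dataclass
class PipelineResult:
    tables: dict
    manifest: dict
    trend: adapt.SlopeTrend | None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    seeds = stage_seeds(config.seed)
    manifest = {"seed": config.seed,
                "stage_seed_spawn_keys": {k: list(v.spawn_key)
                                          for k, v in seeds.items()},
                "config": config.to_dict(),
                "versions": _versions()}

    # inputs: load, or simulate the default synthetic experiment
    if config.series_csv:
        series = synth.read_series_csv(config.series_csv)
        truths = None
    else:
        truths = synth.make_truth(config.n_strains,
                                  config.adaptation_strength, config.seed)
        series = synth.simulate_experiment(truths, config.design,
                                           seeds["simulate"])
    if config.blank_csv:
        blanks = pd.read_csv(config.blank_csv, comment="#")["rfu"].to_numpy()
    else:
        blanks = synth.simulate_blanks(config.design, seeds["blanks"])
    if config.lake_csv:
        lake_records = synth.read_lake_csv(config.lake_csv)
    elif truths is not None:
        lake_records = synth.make_lake_records(truths, seeds["lakes"])
    else:
        lake_records = None

    wells = series.groupby(["strain", "temperature_C", "phosphorus_umol_L",
                            "replicate"]).ngroups
    threshold = (config.detection_threshold
                 if config.detection_threshold is not None
                 else growth_mod.compute_detection_limit(blanks))
    growth_df = growth_mod.fit_growth_table(series, threshold)
    manifest.update(wells_read=int(wells),
                    wells_excluded=int(wells - len(growth_df)),
                    detection_threshold=float(threshold))

    boot_B = config.bootstrap_B if config.do_bootstrap else None
    tpc_df, ea_df, ea_sum = thermal_stage(
        growth_df, config.tpc_n_starts, seeds["tpc"],
        autpc_range=config.autpc_range, ea_reference=config.ea_reference,
        bootstrap_B=boot_B)
    monod_df = monod_stage(growth_df, config.mortality,
                           config.monod_n_starts, seeds["monod"],
                           bootstrap_B=boot_B)
    manifest.update(n_tpc_fits=int(len(tpc_df)),
                    n_monod_fits=int(len(monod_df)),
                    n_monod_excluded=int((~monod_df["retained"]).sum())
                    if "retained" in monod_df else 0)

    smooth_df = smooth_stage(tpc_df, ea_df, monod_df, k=3,
                             edf_threshold=config.edf_threshold)

    tables = {"series": series, "growth": growth_df, "tpc": tpc_df,
              "ea": ea_df, "ea_summary": ea_sum, "monod": monod_df,
              "smooths": smooth_df}
    trend = None
    if lake_records is not None:
        env_df = lake_stage(lake_records)
        tables["lake_environment"] = env_df
        env = {lake.replace("lake_", ""): p for lake, p in
               zip(env_df["lake"], env_df["mean_phosphorus"])}
        missing = [k for k, v in env.items() if not np.isfinite(v)]
        if missing:
            log.warning("strains without lake chemistry excluded from "
                        "stage-1 regressions: %s", missing)
        slopes, trend = adapt.two_stage(monod_df, env, trait_col="p_star")
        tables["slopes"] = adapt.slopes_to_frame(slopes)
        manifest["trend"] = {"slope": trend.trend_slope,
                             "se": trend.trend_se, "p": trend.trend_p}

    if config.output_dir:
        _write_outputs(tables, manifest, config.output_dir)
    return PipelineResult(tables, manifest, trend)


def run_adaptation_analysis(truths, design, seed, m=0.1,
                            monod_n_starts: int = 6,
                            use_lake_records: bool = True):
    """Fast path from simulation to the stage-2 trend (no TPC stage).

    Used for replicated signal-detection studies: simulate, estimate growth
    rates, fit Monod curves, derive and screen P*, summarize the source
    lakes and run the two-stage regression.  Returns (slopes, trend).
    """
    seeds = stage_seeds(seed)
    series = synth.simulate_experiment(truths, design, seeds["simulate"])
    blanks = synth.simulate_blanks(design, seeds["blanks"])
    threshold = growth_mod.compute_detection_limit(blanks)
    growth_df = growth_mod.fit_growth_table(series, threshold)
    monod_df = monod_stage(growth_df, m, monod_n_starts, seeds["monod"])
    if use_lake_records:
        records = synth.make_lake_records(truths, seeds["lakes"])
        env_df = lake_stage(records)
        env = {lake.replace("lake_", ""): p for lake, p in
               zip(env_df["lake"], env_df["mean_phosphorus"])}
    else:
        env = {t.strain_id: t.source_lake_phosphorus for t in truths}
    return adapt.two_stage(monod_df, env, trait_col="p_star")


def simulate_command(config: PipelineConfig, output_dir=None) -> dict:
    """Write the synthetic dataset (series, blanks, lakes, truth) to disk."""
    out = Path(output_dir or config.output_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    truths = synth.make_truth(config.n_strains, config.adaptation_strength,
                              config.seed)
    series = synth.simulate_experiment(truths, config.design,
                                       seeds["simulate"])
    blanks = synth.simulate_blanks(config.design, seeds["blanks"])
    lake_records = synth.make_lake_records(truths, seeds["lakes"])
    paths = {"series": out / "fluorescence_series.csv",
             "blanks": out / "blank_rfu.csv",
             "lakes": out / "lake_monitoring.csv",
             "truth": out / "truth.json"}
    synth.write_series_csv(series, paths["series"])
    pd.DataFrame({"rfu": blanks}).to_csv(paths["blanks"], index=False)
    synth.write_lake_csv(lake_records, paths["lakes"])
    synth.truths_to_json(truths, paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def _versions() -> dict:
    import scipy
    import statsmodels
    from . import __version__
    return {"phytotraits": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__}


def _write_outputs(tables, manifest, output_dir) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        if isinstance(df, pd.DataFrame):
            with open(out / f"{name}.csv", "w") as fh:
                fh.write(f"# phytotraits schema={name} v1\n")
                df.to_csv(fh, index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
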
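"""Synthetic logger series, global grids and toy country polygons.

The generators emulate the statistical structure the analysis assumes, so
every pipeline stage can run and be validated without any download:

* homes — hourly indoor series that look thermostat-controlled (a per-home
  setpoint, mild seasonal and diurnal cycles, AR(1) noise standing in for
  thermal inertia) paired with outdoor series carrying a full seasonal
  amplitude and a stronger diurnal cycle;
* grids — half-degree-lattice monthly climatologies with a latitudinal
  mean-temperature gradient, seasonal amplitude growing away from the
  equator with the seasonal phase flipped across it, relative humidity
  declining with |latitude|, and vapour pressure derived from the
  generated temperature and humidity through the same Magnus conversion
  the analysis uses (model consistency);
* planted analogues — a chosen cell's 12 monthly values overwritten so its
  seasonal profile equals a given target exactly, the ground truth for
  ranking tests.

Everything is driven by :class:`numpy.random.Generator` seeded from the
config, so the same seed reproduces identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .climate_variables import SeasonalProfile, season_of, vapour_pressure
from .logger_io import HomeDataset

__all__ = [
    "HomeGeneratorConfig",
    "GridGeneratorConfig",
    "generate_home_series",
    "generate_grid",
    "plant_analogue",
    "toy_countries",
    "write_homes",
]


@dataclass(frozen=True)
class HomeGeneratorConfig:
    """Knobs for the hourly home-logger generator.

    Defaults mirror the deployment the analysis is built around: 37 US
    homes logged hourly from February 2013 through April 2014.  The indoor
    seasonal amplitude (3 degC about a 21.5 degC setpoint) and the 2.5 degC
    between-home spread reproduce the magnitude of winter-minimum /
    summer-maximum separation observed in lived-in, thermostat-controlled
    homes; outdoor settings are mid-latitude continental (12 +/- 12 degC
    annual cycle, 5 degC diurnal swing).
    """

    seed: int = 0
    n_homes: int = 37
    start: str = "2013-02-01"
    end: str = "2014-04-30"
    thermostat_setpoint: float = 21.5  # degC, population mean
    between_home_sd: float = 2.5  # degC, spread of per-home setpoints
    indoor_seasonal_amplitude: float = 3.0  # degC, indoor winter-summer drift
    indoor_diurnal_amplitude: float = 1.0  # degC
    setpoint_tightness: float = 1.0  # degC, stationary SD of indoor AR(1) noise
    indoor_rh_mean: float = 48.0  # %
    indoor_rh_between_sd: float = 6.0  # %
    indoor_rh_sd: float = 5.0  # %, hourly AR(1) noise
    outdoor_annual_mean: float = 12.0  # degC
    outdoor_annual_amplitude: float = 12.0  # degC
    diurnal_amplitude: float = 5.0  # degC, outdoor
    outdoor_rh_mean: float = 70.0  # %
    outdoor_rh_sd: float = 10.0  # %
    noise_sd: float = 1.5  # degC, outdoor hourly AR(1) noise
    ar1: float = 0.9  # hourly autocorrelation (thermal inertia)
    lat_range: tuple[float, float] = (30.0, 48.0)
    lon_range: tuple[float, float] = (-120.0, -75.0)
    #: home index -> calendar months (1..12) to delete, for QC-failing homes
    drop_months: Mapping[int, Sequence[int]] = field(default_factory=dict)


@dataclass(frozen=True)
class GridGeneratorConfig:
    """Knobs for the monthly gridded-climatology generator.

    Cells sit on the half-degree lattice.  Monthly mean temperature is
    ``equator_mean_T - pole_gradient*|lat| + amp(lat) * cos(2*pi*(month -
    peak)/12)`` with ``amp(lat) = base_amplitude + amplitude_per_degree *
    |lat|`` and the peak month July north of the equator, January south of
    it.  Daily extrema are a fixed half-range about the mean; relative
    humidity falls linearly with |lat| and vapour pressure follows from T
    and RH.
    """

    seed: int = 0
    lat_min: float = -29.75
    lat_max: float = 29.75
    lon_min: float = -9.75
    lon_max: float = 9.75
    equator_mean_T: float = 26.0  # degC at the equator
    pole_gradient: float = 0.55  # degC lost per degree of |lat|
    base_amplitude: float = 1.0  # degC seasonal amplitude at the equator
    amplitude_per_degree: float = 0.25  # degC of amplitude per degree |lat|
    t_half_range: float = 5.0  # degC, t_mean -> daily min/max offset
    rh_at_equator: float = 80.0  # %
    rh_lat_slope: float = 0.4  # % lost per degree |lat|
    noise_sd: float = 0.0  # degC, per-(cell, month) noise


def _ar1(rng: np.random.Generator, n: int, phi: float, stationary_sd: float) -> np.ndarray:
    if stationary_sd == 0 or n == 0:
        return np.zeros(n)
    eps_sd = stationary_sd * np.sqrt(max(1.0 - phi**2, 1e-12))
    eps = rng.standard_normal(n) * eps_sd
    x = lfilter([1.0], [1.0, -phi], eps)
    return x


def generate_home_series(cfg: HomeGeneratorConfig = HomeGeneratorConfig()) -> list[HomeDataset]:
    """Generate paired indoor/outdoor hourly series for ``cfg.n_homes`` homes."""
    rng = np.random.default_rng(cfg.seed)
    ts = pd.date_range(cfg.start, cfg.end, freq="h")
    hours = ts.hour.to_numpy()
    doy = ts.dayofyear.to_numpy()
    annual = np.cos(2 * np.pi * (doy - 196) / 365.25)  # peaks mid-July
    diurnal = np.cos(2 * np.pi * (hours - 15) / 24)  # peaks mid-afternoon

    homes = []
    for i in range(cfg.n_homes):
        setpoint = cfg.thermostat_setpoint + cfg.between_home_sd * rng.standard_normal()
        rh_base = cfg.indoor_rh_mean + cfg.indoor_rh_between_sd * rng.standard_normal()
        lat = rng.uniform(*cfg.lat_range)
        lon = rng.uniform(*cfg.lon_range)

        t_in = (
            setpoint
            + cfg.indoor_seasonal_amplitude * annual
            + cfg.indoor_diurnal_amplitude * diurnal
            + _ar1(rng, len(ts), cfg.ar1, cfg.setpoint_tightness)
        )
        rh_in = np.clip(
            rh_base
            + 8.0 * annual  # indoor air is moister in summer
            + _ar1(rng, len(ts), cfg.ar1, cfg.indoor_rh_sd),
            0,
            100,
        )
        t_out = (
            cfg.outdoor_annual_mean
            + cfg.outdoor_annual_amplitude * annual
            + cfg.diurnal_amplitude * diurnal
            + _ar1(rng, len(ts), cfg.ar1, cfg.noise_sd)
        )
        rh_out = np.clip(
            cfg.outdoor_rh_mean + _ar1(rng, len(ts), cfg.ar1, cfg.outdoor_rh_sd), 0, 100
        )

        indoor = pd.DataFrame(
            {"timestamp": ts, "temperature": t_in, "relative_humidity": rh_in}
        )
        outdoor = pd.DataFrame(
            {"timestamp": ts, "temperature": t_out, "relative_humidity": rh_out}
        )
        if i in cfg.drop_months:
            bad = set(int(m) for m in cfg.drop_months[i])
            keep = ~indoor["timestamp"].dt.month.isin(bad)
            indoor = indoor.loc[keep].reset_index(drop=True)
            outdoor = outdoor.loc[keep].reset_index(drop=True)
        homes.append(
            HomeDataset(
                home_id=f"home{i:02d}",
                indoor=indoor,
                outdoor=outdoor,
                state=f"SynthState-{i:02d}",
                latitude=float(lat),
                longitude=float(lon),
            )
        )
    return homes


def generate_grid(cfg: GridGeneratorConfig = GridGeneratorConfig()) -> pd.DataFrame:
    """Generate a long-format monthly grid (same schema the readers return)."""
    lats = np.arange(cfg.lat_min, cfg.lat_max + 1e-9, 0.5)
    lons = np.arange(cfg.lon_min, cfg.lon_max + 1e-9, 0.5)
    if lats.size == 0 or lons.size == 0:
        raise ValueError("empty grid extent")
    rng = np.random.default_rng(cfg.seed)

    lat_g, lon_g, month_g = np.meshgrid(lats, lons, np.arange(1, 13), indexing="ij")
    lat_f, lon_f, month_f = lat_g.ravel(), lon_g.ravel(), month_g.ravel()

    abs_lat = np.abs(lat_f)
    base = cfg.equator_mean_T - cfg.pole_gradient * abs_lat
    amp = cfg.base_amplitude + cfg.amplitude_per_degree * abs_lat
    peak = np.where(lat_f > 0, 7, 1)  # July north of the equator, January south
    t_mean = base + amp * np.cos(2 * np.pi * (month_f - peak) / 12.0)
    if cfg.noise_sd > 0:
        t_mean = t_mean + rng.normal(0, cfg.noise_sd, size=t_mean.shape)
    rh = np.clip(cfg.rh_at_equator - cfg.rh_lat_slope * abs_lat, 5, 100)
    grid = pd.DataFrame(
        {
            "lat": lat_f,
            "lon": lon_f,
            "month": month_f.astype(int),
            "t_mean": t_mean,
            "t_min": t_mean - cfg.t_half_range,
            "t_max": t_mean + cfg.t_half_range,
            "vp_mean": vapour_pressure(t_mean, rh),
        }
    )
    return grid.sort_values(["lat", "lon", "month"], kind="mergesort").reset_index(drop=True)


def expected_cell_profile(cfg: GridGeneratorConfig, lat: float) -> SeasonalProfile:
    """Closed-form seasonal profile of a noise-free generated cell.

    Independent of the pipeline's aggregation code: evaluates the generator
    formula month by month and averages per season directly.
    """
    abs_lat = abs(lat)
    base = cfg.equator_mean_T - cfg.pole_gradient * abs_lat
    amp = cfg.base_amplitude + cfg.amplitude_per_degree * abs_lat
    peak = 7 if lat > 0 else 1
    rh = float(np.clip(cfg.rh_at_equator - cfg.rh_lat_slope * abs_lat, 5, 100))
    hemi = "S" if lat < 0 else "N"

    by_season: dict[str, list[tuple[float, float]]] = {}
    for month in range(1, 13):
        t = base + amp * np.cos(2 * np.pi * (month - peak) / 12.0)
        by_season.setdefault(season_of(month, hemi), []).append(
            (float(t), float(vapour_pressure(t, rh)))
        )
    mean = lambda pairs, j: float(np.mean([p[j] for p in pairs]))
    inter_t = np.mean([mean(by_season["spring"], 0), mean(by_season["autumn"], 0)])
    inter_v = np.mean([mean(by_season["spring"], 1), mean(by_season["autumn"], 1)])
    return SeasonalProfile(
        winter_tmin=mean(by_season["winter"], 0) - cfg.t_half_range,
        winter_vp=mean(by_season["winter"], 1),
        interseason_tmean=float(inter_t),
        interseason_vp=float(inter_v),
        summer_tmax=mean(by_season["summer"], 0) + cfg.t_half_range,
        summer_vp=mean(by_season["summer"], 1),
    )


def plant_analogue(
    grid: pd.DataFrame, profile: SeasonalProfile, at: tuple[float, float]
) -> pd.DataFrame:
    """Overwrite one cell so its seasonal profile equals ``profile`` exactly.

    Each month receives its season's target value for every temperature
    column (min = mean = max) and the season's vapour pressure, so the
    aggregation recovers the target with no residual.  Returns a modified
    copy; raises ``KeyError`` if the cell is absent.
    """
    lat, lon = at
    mask = np.isclose(grid["lat"], lat) & np.isclose(grid["lon"], lon)
    if int(mask.sum()) != 12:
        raise KeyError(f"cell ({lat}, {lon}) not present with 12 months")
    hemi = "S" if lat < 0 else "N"
    season_t = {
        "winter": profile.winter_tmin,
        "spring": profile.interseason_tmean,
        "autumn": profile.interseason_tmean,
        "summer": profile.summer_tmax,
    }
    season_v = {
        "winter": profile.winter_vp,
        "spring": profile.interseason_vp,
        "autumn": profile.interseason_vp,
        "summer": profile.summer_vp,
    }
    out = grid.copy()
    months = out.loc[mask, "month"].astype(int)
    seasons = [season_of(m, hemi) for m in months]
    t_vals = np.array([season_t[s] for s in seasons])
    v_vals = np.array([season_v[s] for s in seasons])
    out.loc[mask, "t_mean"] = t_vals
    out.loc[mask, "t_min"] = t_vals
    out.loc[mask, "t_max"] = t_vals
    out.loc[mask, "vp_mean"] = v_vals
    return out


def toy_countries(
    bounds: tuple[float, float, float, float], names: Sequence[str]
) -> dict:
    """GeoJSON FeatureCollection of vertical rectangle "countries".

    ``bounds`` = (lon_min, lat_min, lon_max, lat_max); the extent is split
    into ``len(names)`` equal longitude bands.
    """
    lon_min, lat_min, lon_max, lat_max = bounds
    edges = np.linspace(lon_min, lon_max, len(names) + 1)
    features = []
    for name, x0, x1 in zip(names, edges[:-1], edges[1:]):
        ring = [
            [float(x0), float(lat_min)],
            [float(x1), float(lat_min)],
            [float(x1), float(lat_max)],
            [float(x0), float(lat_max)],
            [float(x0), float(lat_min)],
        ]
        features.append(
            {
                "type": "Feature",
                "properties": {"name": name},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_homes(
    homes: Sequence[HomeDataset], outdir: str | Path, float_format: str = "%.4f"
) -> Path:
    """Write per-home indoor/outdoor CSVs plus a ``homes.csv`` manifest.

    Files use the same default dialect :func:`climalogue.logger_io.
    read_logger_table` expects, making write->read a round trip.  Values
    are serialized at fixed precision so outputs are platform-stable.
    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for home in homes:
        paths = {}
        for side in ("indoor", "outdoor"):
            series = getattr(home, side)
            if series is None:
                paths[side] = ""
                continue
            p = outdir / f"{home.home_id}_{side}.csv"
            series.to_csv(p, index=False, float_format=float_format)
            paths[side] = p.name
        rows.append(
            {
                "home_id": home.home_id,
                "state": home.state,
                "latitude": home.latitude,
                "longitude": home.longitude,
                "indoor_file": paths["indoor"],
                "outdoor_file": paths["outdoor"],
            }
        )
    manifest = outdir / "homes.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def write_toy_countries(gj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(gj))
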
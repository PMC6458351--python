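"""Gridded monthly climatology: readers, per-cell seasonal profiles, countries.

A grid is held as a long-format frame with one row per (cell, month):
columns ``lat, lon, month, t_mean, t_min, t_max, vp_mean`` (degC / hPa).
Cell centres live on the global 0.5 degree lattice (..., -0.25, 0.25, 0.75,
...), so no centre sits exactly on the equator; cells with lat > 0 are
Northern-Hemisphere.  Two readers are provided — CF-style netCDF (lat, lon,
12-step time) and the same long CSV the package writes — and round-trip to
identical profiles.

Country assignment is point-in-polygon on cell centres against GeoJSON
polygons, with a nearest-polygon fallback for coastal centres that fall
just offshore of every polygon.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .climate_variables import (
    PROFILE_FIELDS,
    SeasonalProfile,
    season_of_months,
    seasonal_profile,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_grid",
    "write_grid_csv",
    "write_grid_netcdf",
    "cell_profiles",
    "cell_seasonal_profile",
    "assign_country",
]

GRID_COLUMNS = ["lat", "lon", "month", "t_mean", "t_min", "t_max", "vp_mean"]

#: Default netCDF variable names (CRU-style).
DEFAULT_NC_VARIABLES = {"t_mean": "tmp", "t_min": "tmn", "t_max": "tmx", "vp": "vap"}


def _check_lattice(lat: np.ndarray, lon: np.ndarray, any_grid: bool) -> None:
    if any_grid:
        return
    on_lattice = lambda x: np.allclose(np.mod(x, 0.5), 0.25, atol=1e-6)
    if not (on_lattice(lat) and on_lattice(lon)):
        raise ValueError(
            "cell centres are not on the half-degree lattice (x.25/x.75); "
            "pass any_grid=True to accept arbitrary grids"
        )
    if np.any(np.abs(lat) >= 90) or np.any(lon < -180) or np.any(lon >= 180):
        raise ValueError("lat must lie in (-90, 90) and lon in [-180, 180)")


def _convert_vp(vp: np.ndarray, unit: str) -> np.ndarray:
    if unit == "hPa":
        return vp
    if unit == "Pa":
        return vp / 100.0
    if unit == "0.1hPa":  # climatologies sometimes store tenths
        return vp / 10.0
    raise ValueError(f"unknown vapour-pressure unit {unit!r}")


def read_grid(
    path: str | Path,
    variables: Optional[Mapping[str, str]] = None,
    vp_unit: str = "hPa",
    any_grid: bool = False,
) -> pd.DataFrame:
    """Read a monthly gridded climatology into the long-format grid frame.

    ``path`` ending in ``.nc`` is read as netCDF (dims lat/lon/time with 12
    time steps; variable names via ``variables``, default CRU-style
    tmp/tmn/tmx/vap); anything else as long CSV with the canonical columns.
    Cells with missing values in any month are excluded (that is how a land
    mask is expressed).  When t_min/t_max are absent they fall back to
    t_mean with a loud warning, degrading the winter/summer extrema to
    means rather than failing.
    """
    path = Path(path)
    if path.suffix == ".nc":
        grid = _read_grid_netcdf(path, variables or DEFAULT_NC_VARIABLES)
    else:
        grid = _read_grid_csv(path)
    grid["vp_mean"] = _convert_vp(grid["vp_mean"].to_numpy(dtype=float), vp_unit)
    _check_lattice(grid["lat"].to_numpy(), grid["lon"].to_numpy(), any_grid)

    # drop cells without a complete 12-month record
    counts = grid.groupby(["lat", "lon"])["month"].transform("size")
    incomplete = counts != 12
    if incomplete.any():
        n_cells = grid.loc[incomplete, ["lat", "lon"]].drop_duplicates().shape[0]
        logger.info("excluding %d cell(s) without 12 complete months", n_cells)
        grid = grid.loc[~incomplete]
    if grid.empty:
        raise ValueError(f"{path}: no complete grid cells")
    return grid.sort_values(["lat", "lon", "month"], kind="mergesort").reset_index(drop=True)


def _read_grid_csv(path: Path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    rename = {"vp": "vp_mean"}
    raw = raw.rename(columns=rename)
    missing = [c for c in ("lat", "lon", "month", "t_mean", "vp_mean") if c not in raw.columns]
    if missing:
        raise KeyError(f"grid CSV {path} lacks column(s) {missing}")
    for col, fallback in (("t_min", "t_mean"), ("t_max", "t_mean")):
        if col not in raw.columns:
            logger.warning("%s: %s absent; falling back to t_mean", path.name, col)
            raw[col] = raw[fallback]
    grid = raw[GRID_COLUMNS].dropna()
    return grid


def _read_grid_netcdf(path: Path, variables: Mapping[str, str]) -> pd.DataFrame:
    import xarray as xr

    ds = xr.open_dataset(path, engine="scipy")
    name_tm = variables.get("t_mean", "tmp")
    name_vp = variables.get("vp", "vap")
    for required, name in (("t_mean", name_tm), ("vp", name_vp)):
        if name not in ds:
            raise KeyError(f"netCDF {path} lacks variable {name!r} ({required})")
    if ds.sizes.get("time") != 12:
        raise ValueError(f"netCDF {path} must have exactly 12 time steps")

    frames = {"t_mean": ds[name_tm], "vp_mean": ds[name_vp]}
    for key, fallback in (("t_min", "t_mean"), ("t_max", "t_mean")):
        name = variables.get(key)
        if name and name in ds:
            frames[key] = ds[name]
        else:
            logger.warning("%s: %s absent; falling back to t_mean", path.name, key)
            frames[key] = frames[fallback]

    df = xr.Dataset(frames).to_dataframe().reset_index()
    # month 1..12 from the time axis position
    time_vals = list(ds["time"].values)
    month_of = {t: i + 1 for i, t in enumerate(time_vals)}
    df["month"] = df["time"].map(month_of)
    df = df.drop(columns=["time"]).dropna()
    return df[GRID_COLUMNS]


def write_grid_csv(grid: pd.DataFrame, path: str | Path) -> None:
    grid[GRID_COLUMNS].to_csv(path, index=False)


def write_grid_netcdf(
    grid: pd.DataFrame, path: str | Path, variables: Optional[Mapping[str, str]] = None
) -> None:
    """Write the long-format grid as CF-style netCDF (classic format)."""
    import xarray as xr

    names = dict(DEFAULT_NC_VARIABLES)
    if variables:
        names.update(variables)
    wide = grid.set_index(["lat", "lon", "month"]).to_xarray()
    wide = wide.rename(
        {
            "month": "time",
            "t_mean": names["t_mean"],
            "t_min": names["t_min"],
            "t_max": names["t_max"],
            "vp_mean": names["vp"],
        }
    )
    wide.to_netcdf(path, engine="scipy")


def cell_profiles(grid: pd.DataFrame) -> pd.DataFrame:
    """Hemisphere-aware seasonal profiles for every grid cell, vectorized.

    Returns a frame indexed by (lat, lon) with the six profile columns.
    Cells south of the equator use flipped season assignments, so a
    Southern series equal to a Northern one shifted six months yields an
    identical profile.
    """
    g = grid.copy()
    southern = g["lat"].to_numpy() < 0
    g["season"] = season_of_months(g["month"].to_numpy(int), southern)

    def season_agg(season: str, col: str) -> pd.Series:
        sub = g[g["season"] == season]
        return sub.groupby(["lat", "lon"])[col].mean()

    winter_tmin = season_agg("winter", "t_min")
    winter_vp = season_agg("winter", "vp_mean")
    summer_tmax = season_agg("summer", "t_max")
    summer_vp = season_agg("summer", "vp_mean")
    spring_t = season_agg("spring", "t_mean")
    spring_vp = season_agg("spring", "vp_mean")
    autumn_t = season_agg("autumn", "t_mean")
    autumn_vp = season_agg("autumn", "vp_mean")

    out = pd.DataFrame(
        {
            "winter_tmin": winter_tmin,
            "winter_vp": winter_vp,
            "interseason_tmean": (spring_t + autumn_t) / 2.0,
            "interseason_vp": (spring_vp + autumn_vp) / 2.0,
            "summer_tmax": summer_tmax,
            "summer_vp": summer_vp,
        }
    )
    out = out.dropna()
    return out[list(PROFILE_FIELDS)].sort_index()


def cell_seasonal_profile(cell_monthly: pd.DataFrame, lat: float) -> SeasonalProfile:
    """Seasonal profile of one cell's 12-month record (hemisphere from ``lat``)."""
    hemi = "S" if lat < 0 else "N"
    return seasonal_profile(cell_monthly, hemisphere=hemi)


def _feature_name(props: Mapping) -> str:
    for key in ("name", "NAME", "admin", "ADMIN", "country", "COUNTRY"):
        if props.get(key):
            return str(props[key])
    return "unnamed"


def assign_country(
    cells: pd.DataFrame,
    geojson_path: str | Path,
    tolerance: float = 0.5,
) -> pd.Series:
    """Assign each cell centre to a country by point-in-polygon.

    ``cells`` needs ``lat``/``lon`` columns or a (lat, lon) index.  Centres
    inside no polygon take the nearest polygon within ``tolerance`` degrees;
    beyond that they are labelled ``"unassigned"``.  Deterministic: the
    same polygons and cells always give the same labels.
    """
    from shapely.geometry import Point, shape
    from shapely.strtree import STRtree

    path = Path(geojson_path)
    try:
        gj = json.loads(path.read_text())
        features = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
        geoms = [shape(f["geometry"]) for f in features]
        names = [_feature_name(f.get("properties") or {}) for f in features]
    except (OSError, KeyError, ValueError) as exc:
        raise ValueError(f"cannot read country polygons from {path}: {exc}") from exc

    if isinstance(cells.index, pd.MultiIndex):
        lat = cells.index.get_level_values("lat").to_numpy(float)
        lon = cells.index.get_level_values("lon").to_numpy(float)
        index = cells.index
    else:
        lat = cells["lat"].to_numpy(float)
        lon = cells["lon"].to_numpy(float)
        index = cells.index

    tree = STRtree(geoms)
    points = [Point(x, y) for x, y in zip(lon, lat)]
    labels = []
    for pt in points:
        hit = None
        inside = tree.query(pt, predicate="intersects")
        if len(inside):
            hit = names[int(np.min(inside))]  # lowest feature index for determinism
        if hit is None and tolerance > 0:
            idx = tree.nearest(pt)
            if idx is not None and geoms[idx].distance(pt) <= tolerance:
                hit = names[idx]
        labels.append(hit or "unassigned")
    return pd.Series(labels, index=index, name="country")
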
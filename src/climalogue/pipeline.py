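"""End-to-end orchestration: homes + grid + polygons -> analogue reports.

Thin glue over the library modules.  ``run_analogues`` takes a homes
manifest directory (as written by :func:`climalogue.synthetic_data.
write_homes`), a grid file (netCDF or long CSV), and optional country
polygons, and writes the standard outputs: a QC report, per-home seasonal
profiles, a per-home analogue table, the mean-home dissimilarity surface,
and the by-season indoor~outdoor regression table.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import climate_variables as cv
from . import dissimilarity as ds
from . import global_grid as gg
from . import logger_io as io
from . import summaries as sm

logger = logging.getLogger(__name__)

__all__ = ["load_homes", "home_profiles", "run_analogues"]


def load_homes(manifest: str | Path, dialect: io.LoggerDialect = io.DEFAULT_DIALECT) -> list[io.HomeDataset]:
    """Read every home listed in a ``homes.csv`` manifest."""
    manifest = Path(manifest)
    base = manifest.parent
    table = pd.read_csv(manifest)
    homes = []
    for _, row in table.iterrows():
        outdoor = None
        if isinstance(row.get("outdoor_file"), str) and row["outdoor_file"]:
            outdoor = io.read_logger_table(base / row["outdoor_file"], dialect)
        homes.append(
            io.HomeDataset(
                home_id=str(row["home_id"]),
                indoor=io.read_logger_table(base / row["indoor_file"], dialect),
                outdoor=outdoor,
                state=str(row.get("state", "")),
                latitude=None if pd.isna(row.get("latitude")) else float(row["latitude"]),
                longitude=None if pd.isna(row.get("longitude")) else float(row["longitude"]),
            )
        )
    return homes


def home_profiles(
    homes: list[io.HomeDataset],
    minimum_days: int = cv.DEFAULT_MINIMUM_DAYS,
    extrema: str = "daily_extrema",
):
    """QC, monthly summaries, profiles and scales for every retained home.

    Returns ``(qc_frame, profiles_frame, scales, monthly)`` where
    ``profiles_frame`` has one row per retained home, ``scales`` maps
    home_id -> within-home :class:`~climalogue.climate_variables.
    VariableScale`, and ``monthly`` maps home_id -> (indoor, outdoor)
    monthly frames.
    """
    reports, rows, scales, monthly = [], {}, {}, {}
    for home in homes:
        report = io.qc_season_coverage(home, minimum_days=minimum_days)
        reports.append(report)
        if not report.retained:
            continue
        months_in = cv.monthly_summaries(home.indoor, minimum_days=minimum_days)
        profile = cv.seasonal_profile(months_in, home.hemisphere, extrema=extrema)
        rows[home.home_id] = profile
        scales[home.home_id] = cv.indoor_scales(
            months_in, mode="within_home_months", hemisphere=home.hemisphere, extrema=extrema
        )
        months_out = (
            cv.monthly_summaries(home.outdoor, minimum_days=minimum_days)
            if home.outdoor is not None
            else None
        )
        monthly[home.home_id] = (months_in, months_out)
    qc = io.qc_report_frame(reports)
    profiles = cv.profiles_frame(rows)
    return qc, profiles, scales, monthly


def run_analogues(
    homes_manifest: str | Path,
    grid_path: str | Path,
    countries_path: Optional[str | Path] = None,
    out_dir: str | Path = "results",
    top_n: int = 100,
    sqrt_mode: bool = True,
    minimum_days: int = cv.DEFAULT_MINIMUM_DAYS,
) -> dict:
    """Full pipeline; writes CSV outputs under ``out_dir`` and returns them.

    Outputs: ``qc_report.csv``, ``home_profiles.csv``, ``analogue_table.csv``
    (one row per retained home: nearest cell, C, country, top-n mean/SE and
    modal country), ``mean_home_surface.csv`` (per-cell C for the mean
    focal climate), and ``regression_table.csv`` when outdoor series exist.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    homes = load_homes(homes_manifest)
    qc, profiles, scales, monthly = home_profiles(homes, minimum_days=minimum_days)
    if profiles.empty:
        raise ValueError("no home passed season-coverage QC")

    grid = gg.read_grid(grid_path)
    cells = gg.cell_profiles(grid)
    countries = (
        gg.assign_country(cells, countries_path) if countries_path is not None else None
    )

    rows = []
    for home_id, profile_row in profiles.iterrows():
        profile = cv.SeasonalProfile.from_array(profile_row.to_numpy())
        result = ds.rank_analogues(
            profile, scales[home_id], cells, n=top_n, sqrt_mode=sqrt_mode,
            countries=countries, home_id=str(home_id),
        )
        rows.append(
            {
                "home_id": home_id,
                "C_nearest": result.nearest.C,
                "nearest_country": result.nearest_country,
                "nearest_lat": result.nearest.lat,
                "nearest_lon": result.nearest.lon,
                f"C_top{top_n}_mean": result.top_n_mean_C,
                f"C_top{top_n}_se": result.top_n_se_C,
                "modal_country": result.top_n_modal_country,
            }
        )
    analogue_table = pd.DataFrame(rows)

    mean_result = ds.mean_home_analysis(
        profiles, cells, n=min(top_n, len(cells)), sqrt_mode=sqrt_mode, countries=countries
    )

    pairs = []
    for home in homes:
        if home.home_id not in monthly:
            continue
        months_in, months_out = monthly[home.home_id]
        if months_out is not None:
            pairs.append(sm.indoor_outdoor_pairs(months_in, months_out, home.hemisphere))
    regression = sm.regression_table(pd.concat(pairs, ignore_index=True)) if pairs else None

    qc.to_csv(out_dir / "qc_report.csv", index=False)
    profiles.rename_axis("home_id").to_csv(out_dir / "home_profiles.csv")
    analogue_table.to_csv(out_dir / "analogue_table.csv", index=False)
    mean_result.ranked.to_csv(out_dir / "mean_home_surface.csv", index=False)
    sm.seasonal_descriptives(profiles).to_csv(out_dir / "seasonal_descriptives.csv", index=False)
    if regression is not None:
        regression.to_csv(out_dir / "regression_table.csv", index=False)

    return {
        "qc": qc,
        "profiles": profiles,
        "analogue_table": analogue_table,
        "mean_home": mean_result,
        "regression": regression,
    }
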
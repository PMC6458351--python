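"""Reading and quality-controlling indoor/outdoor logger series.

Hourly temperature/relative-humidity loggers (iButton-style) export
delimited text with locally-chosen column names and timestamp dialects; the
reader maps those onto a fixed schema and applies conservative cleaning:
humidity clipped to [0, 100] % (sensor saturation near 100 % RH is common),
temperatures outside [-60, 60] degC dropped as sensor faults, duplicate
timestamps averaged.

A home enters the analysis only if its indoor record covers winter, summer
and at least one of spring/autumn; a season counts as present when some
calendar month of that season has at least ``minimum_days`` distinct days
of data, so a stray hour cannot establish a season.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .climate_variables import DEFAULT_MINIMUM_DAYS, season_of

logger = logging.getLogger(__name__)

__all__ = [
    "LoggerDialect",
    "HomeDataset",
    "QCReport",
    "read_logger_table",
    "qc_season_coverage",
    "qc_report_frame",
]

TEMP_BOUNDS = (-60.0, 60.0)


@dataclass(frozen=True)
class LoggerDialect:
    """Column mapping and parsing options for a logger export."""

    timestamp: str = "timestamp"
    temperature: str = "temperature"
    relative_humidity: str = "relative_humidity"
    timestamp_format: Optional[str] = None  # None -> inferred (ISO-8601 etc.)
    sep: str = ","


DEFAULT_DIALECT = LoggerDialect()


@dataclass
class HomeDataset:
    """One home's paired indoor/outdoor hourly series plus metadata."""

    home_id: str
    indoor: pd.DataFrame
    outdoor: Optional[pd.DataFrame] = None
    state: str = ""
    latitude: Optional[float] = None
    longitude: Optional[float] = None

    @property
    def hemisphere(self) -> str:
        """'S' when the home lies south of the equator, else 'N' (the default)."""
        if self.latitude is not None and self.latitude < 0:
            return "S"
        return "N"


@dataclass(frozen=True)
class QCReport:
    home_id: str
    seasons_present: frozenset[str]
    retained: bool
    reason: str


def read_logger_table(
    path: str | Path, dialect: LoggerDialect = DEFAULT_DIALECT
) -> pd.DataFrame:
    """Read one logger export into the canonical observation frame.

    Returns a frame with columns ``timestamp`` (datetime64), ``temperature``
    (degC) and ``relative_humidity`` (%), sorted by timestamp with duplicate
    timestamps collapsed by mean.  Unparseable rows and out-of-range
    temperatures are dropped and counted in the log; humidity is clipped
    into [0, 100].

    Raises
    ------
    KeyError
        if a mandatory column is missing (the message names it).
    ValueError
        if no parseable observation remains.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=dialect.sep)
    for col in (dialect.timestamp, dialect.temperature, dialect.relative_humidity):
        if col not in raw.columns:
            raise KeyError(f"mandatory column {col!r} missing from {path}")

    ts = pd.to_datetime(
        raw[dialect.timestamp], format=dialect.timestamp_format, errors="coerce"
    )
    temp = pd.to_numeric(raw[dialect.temperature], errors="coerce")
    rh = pd.to_numeric(raw[dialect.relative_humidity], errors="coerce")

    obs = pd.DataFrame(
        {"timestamp": ts, "temperature": temp, "relative_humidity": rh}
    )
    n_raw = len(obs)
    obs = obs.dropna()
    bad_temp = (obs["temperature"] < TEMP_BOUNDS[0]) | (obs["temperature"] > TEMP_BOUNDS[1])
    if bad_temp.any():
        logger.warning(
            "%s: dropped %d temperature reading(s) outside %s degC",
            path.name,
            int(bad_temp.sum()),
            TEMP_BOUNDS,
        )
        obs = obs.loc[~bad_temp]
    clipped = (obs["relative_humidity"] < 0) | (obs["relative_humidity"] > 100)
    if clipped.any():
        logger.warning(
            "%s: clipped %d humidity reading(s) into [0, 100] %%",
            path.name,
            int(clipped.sum()),
        )
        obs["relative_humidity"] = obs["relative_humidity"].clip(0, 100)

    dropped = n_raw - len(obs)
    if dropped:
        logger.info("%s: %d unparseable/invalid row(s) dropped", path.name, dropped)
    if obs.empty:
        raise ValueError(f"{path}: zero parseable observations")

    obs = (
        obs.groupby("timestamp", as_index=False)[["temperature", "relative_humidity"]]
        .mean()
        .sort_values("timestamp", kind="mergesort")
        .reset_index(drop=True)
    )
    return obs


def qc_season_coverage(
    home: HomeDataset,
    hemisphere: Optional[str] = None,
    minimum_days: int = DEFAULT_MINIMUM_DAYS,
) -> QCReport:
    """Apply the season-coverage retention rule to one home.

    Retained iff seasons present cover {winter, summer} and intersect
    {spring, autumn}; a season is present iff at least one of its calendar
    months has >= ``minimum_days`` distinct days of indoor data.
    """
    hemi = hemisphere or home.hemisphere
    if home.indoor is None or home.indoor.empty:
        return QCReport(home.home_id, frozenset(), False, "no data")

    ts = pd.to_datetime(home.indoor["timestamp"])
    days = pd.DataFrame(
        {"year": ts.dt.year, "month": ts.dt.month, "date": ts.dt.normalize()}
    )
    per_month = days.groupby(["year", "month"])["date"].nunique()
    full_months = [m for (_, m), n in per_month.items() if n >= minimum_days]
    seasons = frozenset(season_of(m, hemi) for m in full_months)

    missing = {"winter", "summer"} - seasons
    has_shoulder = bool(seasons & {"spring", "autumn"})
    retained = not missing and has_shoulder
    if retained:
        reason = "ok"
    elif missing:
        reason = "missing " + " and ".join(sorted(missing))
    else:
        reason = "missing spring/autumn"
    return QCReport(home.home_id, seasons, retained, reason)


def qc_report_frame(reports: Sequence[QCReport]) -> pd.DataFrame:
    """Tabulate QC reports for CSV export."""
    return pd.DataFrame(
        {
            "home_id": [r.home_id for r in reports],
            "seasons_present": ["|".join(sorted(r.seasons_present)) for r in reports],
            "retained": [r.retained for r in reports],
            "reason": [r.reason for r in reports],
        }
    )
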
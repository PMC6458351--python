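"""Seasonal climate variables shared by indoor loggers and grid cells.

The analysis reduces any monthly climate record — a home's logger series or
a grid cell's climatology — to a six-variable seasonal profile:

* winter:        mean of the monthly mean-daily-minimum temperature, and
                 mean vapour pressure;
* spring/autumn: mean temperature and mean vapour pressure, the two
                 transitional seasons pooled into one "interseason" value;
* summer:        mean of the monthly mean-daily-maximum temperature, and
                 mean vapour pressure.

Humidity is expressed as water vapour pressure (hPa), derived from
temperature and relative humidity through the August–Roche–Magnus
saturation formula, so that indoor loggers (which record RH) and gridded
climatologies (which ship vapour pressure) live on a common scale.

Seasons follow the meteorological convention with a hemisphere flip:
DJF/MAM/JJA/SON are winter/spring/summer/autumn north of the equator and
summer/autumn/winter/spring south of it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MagnusCoefficients",
    "MAGNUS_ALDUCHOV_ESKRIDGE",
    "MAGNUS_WMO",
    "SeasonalProfile",
    "VariableScale",
    "PROFILE_FIELDS",
    "SEASONS",
    "saturation_vapour_pressure",
    "vapour_pressure",
    "season_of",
    "season_of_months",
    "monthly_summaries",
    "seasonal_profile",
    "indoor_scales",
]


class MagnusCoefficients(NamedTuple):
    """Coefficients of e_s(T) = a * exp(b*T / (T + c)), T in degC, e_s in hPa."""

    a: float
    b: float
    c: float


#: Alduchov & Eskridge (1996) fit; accurate to <0.4% over -40..50 degC.
MAGNUS_ALDUCHOV_ESKRIDGE = MagnusCoefficients(6.1094, 17.625, 243.04)
#: WMO/Sonntag-style variant, selectable by config.
MAGNUS_WMO = MagnusCoefficients(6.112, 17.62, 243.12)

DEFAULT_MAGNUS = MAGNUS_ALDUCHOV_ESKRIDGE

#: Canonical ordering of the six-variable seasonal profile.
PROFILE_FIELDS = (
    "winter_tmin",
    "winter_vp",
    "interseason_tmean",
    "interseason_vp",
    "summer_tmax",
    "summer_vp",
)

SEASONS = ("winter", "spring", "summer", "autumn")

#: Month -> Northern-Hemisphere season. Southern Hemisphere flips
#: winter<->summer and spring<->autumn.
_NH_SEASON = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}
_SH_FLIP = {"winter": "summer", "summer": "winter", "spring": "autumn", "autumn": "spring"}

#: Default minimum number of distinct days for a (year, month) to count.
DEFAULT_MINIMUM_DAYS = 14

#: Floor for standard-deviation scales (native units). Thermostat-controlled
#: homes can have near-zero variance in some variables, and the
#: dissimilarity index divides by the squared scale.
DEFAULT_SCALE_FLOOR = 0.1


@dataclass(frozen=True)
class SeasonalProfile:
    """Six-variable seasonal climate vector (temperatures degC, vapour pressure hPa)."""

    winter_tmin: float
    winter_vp: float
    interseason_tmean: float
    interseason_vp: float
    summer_tmax: float
    summer_vp: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"seasonal profile has non-finite entries: {arr}")
        if self.winter_tmin > self.summer_tmax:
            warnings.warn(
                "winter_tmin exceeds summer_tmax; physically unusual profile",
                stacklevel=2,
            )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PROFILE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "SeasonalProfile":
        vals = list(map(float, values))
        if len(vals) != 6:
            raise ValueError(f"expected 6 values, got {len(vals)}")
        return cls(*vals)


@dataclass(frozen=True)
class VariableScale:
    """Per-variable standard deviations used to standardize the dissimilarity index."""

    s: tuple[float, float, float, float, float, float]

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(f"scales must be finite and > 0, got {arr}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.s, dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "VariableScale":
        vals = tuple(map(float, values))
        if len(vals) != 6:
            raise ValueError(f"expected 6 scales, got {len(vals)}")
        return cls(vals)


def saturation_vapour_pressure(
    temperature_c, coefficients: MagnusCoefficients = DEFAULT_MAGNUS
):
    """Saturation vapour pressure e_s (hPa) over water at ``temperature_c`` (degC).

    Uses the August–Roche–Magnus form ``a * exp(b*T / (T + c))``; strictly
    increasing in T.  Scalar in, scalar out; array in, array out.
    """
    t = np.asarray(temperature_c, dtype=float)
    a, b, c = coefficients
    if np.any(t <= -c):
        raise ValueError(f"temperature at or below the Magnus singularity -{c} degC")
    out = a * np.exp(b * t / (t + c))
    return float(out) if np.isscalar(temperature_c) else out


def vapour_pressure(
    temperature_c, relative_humidity_pct, coefficients: MagnusCoefficients = DEFAULT_MAGNUS
):
    """Actual vapour pressure (hPa) from temperature (degC) and RH (%)."""
    rh = np.asarray(relative_humidity_pct, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must lie in [0, 100] %")
    out = (rh / 100.0) * saturation_vapour_pressure(
        np.asarray(temperature_c, dtype=float), coefficients
    )
    return float(out) if np.isscalar(temperature_c) and np.isscalar(relative_humidity_pct) else out


def season_of(month: int, hemisphere: str = "N") -> str:
    """Meteorological season of a calendar month, hemisphere-aware."""
    if month not in _NH_SEASON:
        raise ValueError(f"month must be 1..12, got {month}")
    season = _NH_SEASON[month]
    if hemisphere.upper().startswith("S"):
        season = _SH_FLIP[season]
    elif not hemisphere.upper().startswith("N"):
        raise ValueError(f"hemisphere must be 'N' or 'S', got {hemisphere!r}")
    return season


def season_of_months(months: np.ndarray, southern: np.ndarray) -> np.ndarray:
    """Vectorized :func:`season_of`: months (1..12) and a boolean southern mask."""
    months = np.asarray(months)
    nh = np.array([_NH_SEASON[m] for m in range(1, 13)])
    sh = np.array([_SH_FLIP[s] for s in nh])
    out = nh[months - 1]
    southern = np.asarray(southern, dtype=bool)
    out = np.where(southern, sh[months - 1], out)
    return out


def monthly_summaries(
    observations: pd.DataFrame,
    minimum_days: int = DEFAULT_MINIMUM_DAYS,
    coefficients: MagnusCoefficients = DEFAULT_MAGNUS,
) -> pd.DataFrame:
    """Collapse an hourly logger series to per-calendar-month climate values.

    Parameters
    ----------
    observations
        Frame with columns ``timestamp`` (datetime64), ``temperature`` (degC)
        and ``relative_humidity`` (%), as produced by
        :func:`climalogue.logger_io.read_logger_table`.
    minimum_days
        Months with fewer distinct days of data are omitted (and logged).

    Returns
    -------
    DataFrame with one row per retained (year, month) and columns
    ``year, month, t_mean, t_min, t_max, vp_mean, n_days`` where ``t_min`` /
    ``t_max`` are the means over days of the daily minimum / maximum hourly
    temperature.  Vapour pressure is converted per hourly observation and
    then averaged — not computed from monthly-mean T and RH — because the
    conversion is nonlinear in temperature.
    """
    if observations.empty:
        return pd.DataFrame(
            columns=["year", "month", "t_mean", "t_min", "t_max", "vp_mean", "n_days"]
        )
    obs = observations.copy()
    ts = pd.to_datetime(obs["timestamp"])
    obs["vp"] = vapour_pressure(
        obs["temperature"].to_numpy(), obs["relative_humidity"].to_numpy(), coefficients
    )
    obs["year"] = ts.dt.year
    obs["month"] = ts.dt.month
    obs["date"] = ts.dt.normalize()

    daily = obs.groupby(["year", "month", "date"], sort=True)["temperature"].agg(
        ["min", "max"]
    )
    per_day = daily.groupby(["year", "month"]).mean()

    grouped = obs.groupby(["year", "month"], sort=True)
    out = pd.DataFrame(
        {
            "t_mean": grouped["temperature"].mean(),
            "t_min": per_day["min"],
            "t_max": per_day["max"],
            "vp_mean": grouped["vp"].mean(),
            "n_days": grouped["date"].nunique(),
        }
    ).reset_index()

    thin = out["n_days"] < minimum_days
    if thin.any():
        dropped = out.loc[thin, ["year", "month"]].itertuples(index=False)
        logger.info(
            "omitting %d month(s) below %d days of data: %s",
            int(thin.sum()),
            minimum_days,
            [(r.year, r.month) for r in dropped],
        )
    return out.loc[~thin].reset_index(drop=True)


def _season_means(months: pd.DataFrame, extrema: str) -> dict[str, dict[str, float]]:
    """Per-season aggregates used by :func:`seasonal_profile`."""
    agg: dict[str, dict[str, float]] = {}
    for season, grp in months.groupby("season"):
        if extrema == "daily_extrema":
            tmin = float(grp["t_min"].mean())
            tmax = float(grp["t_max"].mean())
        elif extrema == "monthly_means":
            tmin = float(grp["t_mean"].min())
            tmax = float(grp["t_mean"].max())
        else:
            raise ValueError(f"unknown extrema mode {extrema!r}")
        agg[season] = {
            "tmin": tmin,
            "tmax": tmax,
            "tmean": float(grp["t_mean"].mean()),
            "vp": float(grp["vp_mean"].mean()),
        }
    return agg


def seasonal_profile(
    months: pd.DataFrame,
    hemisphere: str = "N",
    extrema: str = "daily_extrema",
) -> SeasonalProfile:
    """Build the six-variable seasonal profile from monthly climate values.

    Months are pooled by calendar month across years (December joins the
    following January/February purely by calendar month).  Spring and autumn
    are pooled into one interseason value: the mean of the spring aggregate
    and the autumn aggregate when both are present, otherwise whichever one
    is.

    ``extrema`` selects how "minimum/maximum temperature" is read:
    ``"daily_extrema"`` (default) averages the monthly mean-daily-extrema
    columns ``t_min``/``t_max``; ``"monthly_means"`` takes the min/max of
    the monthly mean temperature across the season's months.
    """
    if months.empty:
        raise ValueError("no monthly data: required season 'winter' absent")
    m = months.copy()
    m["season"] = [season_of(int(mo), hemisphere) for mo in m["month"]]
    agg = _season_means(m, extrema)

    for required in ("winter", "summer"):
        if required not in agg:
            raise ValueError(f"required season {required!r} absent from monthly data")
    inter = [agg[s] for s in ("spring", "autumn") if s in agg]
    if not inter:
        raise ValueError("required season 'spring/autumn' absent from monthly data")

    return SeasonalProfile(
        winter_tmin=agg["winter"]["tmin"],
        winter_vp=agg["winter"]["vp"],
        interseason_tmean=float(np.mean([a["tmean"] for a in inter])),
        interseason_vp=float(np.mean([a["vp"] for a in inter])),
        summer_tmax=agg["summer"]["tmax"],
        summer_vp=agg["summer"]["vp"],
    )


def _sd_or_floor(values: np.ndarray, floor: float, label: str) -> float:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        logger.warning("fewer than 2 values for scale %s; using floor %g", label, floor)
        return floor
    return max(float(np.std(values, ddof=1)), floor)


def indoor_scales(
    data: pd.DataFrame,
    mode: str = "within_home_months",
    hemisphere: str = "N",
    floor: float = DEFAULT_SCALE_FLOOR,
    extrema: str = "daily_extrema",
) -> VariableScale:
    """Standard-deviation scales for the six profile variables.

    ``mode="within_home_months"`` (default): ``data`` is one home's monthly
    frame (as from :func:`monthly_summaries`); each scale is the sample SD,
    over that home's contributing months, of the monthly quantity underlying
    the variable (winter months' t_min, pooled spring+autumn months' t_mean,
    summer months' t_max, and the corresponding seasons' vp_mean).

    ``mode="across_homes"``: ``data`` is a frame of per-home seasonal
    profiles (columns = :data:`PROFILE_FIELDS`, one row per home); each
    scale is the SD of that variable across homes.

    Sample (n-1) SDs throughout; every scale is floored at ``floor`` so the
    standardized distance stays defined for near-constant indoor climates.
    """
    if mode == "across_homes":
        missing = [f for f in PROFILE_FIELDS if f not in data.columns]
        if missing:
            raise KeyError(f"profile frame lacks columns {missing}")
        return VariableScale.from_array(
            [_sd_or_floor(data[f].to_numpy(), floor, f) for f in PROFILE_FIELDS]
        )
    if mode != "within_home_months":
        raise ValueError(f"unknown scale mode {mode!r}")

    m = data.copy()
    m["season"] = [season_of(int(mo), hemisphere) for mo in m["month"]]
    tmin_col, tmax_col = ("t_min", "t_max")
    if extrema == "monthly_means":
        tmin_col = tmax_col = "t_mean"
    winter = m[m["season"] == "winter"]
    summer = m[m["season"] == "summer"]
    inter = m[m["season"].isin(["spring", "autumn"])]
    return VariableScale.from_array(
        [
            _sd_or_floor(winter[tmin_col].to_numpy(), floor, "winter_tmin"),
            _sd_or_floor(winter["vp_mean"].to_numpy(), floor, "winter_vp"),
            _sd_or_floor(inter["t_mean"].to_numpy(), floor, "interseason_tmean"),
            _sd_or_floor(inter["vp_mean"].to_numpy(), floor, "interseason_vp"),
            _sd_or_floor(summer[tmax_col].to_numpy(), floor, "summer_tmax"),
            _sd_or_floor(summer["vp_mean"].to_numpy(), floor, "summer_vp"),
        ]
    )


def profiles_frame(profiles: dict[str, SeasonalProfile]) -> pd.DataFrame:
    """Stack named profiles into a tidy frame (index = name, columns = variables)."""
    return pd.DataFrame(
        {name: prof.as_array() for name, prof in profiles.items()},
        index=list(PROFILE_FIELDS),
    ).T
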
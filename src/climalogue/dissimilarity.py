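"""Climate dissimilarity index and analogue ranking.

The dissimilarity between a focal (indoor) seasonal profile h and a grid
cell's profile g is a standardized Euclidean distance over the six seasonal
variables,

    C = sqrt( sum_k (g_k - h_k)^2 / s_k^2 ),

where s_k is a reference standard deviation for variable k (by default the
within-home monthly SD of the focal record).  C is dimensionless and
non-negative, zero exactly when g = h, and invariant to rescaling any
variable jointly in h, g and s.  ``sqrt_mode=False`` reports the un-rooted
sum instead; the two modes rank cells identically, only the reported
magnitude differs.

Ranking is an exhaustive scan over all cells — tens of thousands of cells
by six variables is trivial — with ties broken lexicographically by
(lat, lon) so results are deterministic.  A companion root-mean-square
error splits the six variables by physical type (three temperatures, three
vapour pressures) and reports unstandardized errors in native units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .climate_variables import PROFILE_FIELDS, SeasonalProfile, VariableScale

logger = logging.getLogger(__name__)

__all__ = [
    "DissimilarityRecord",
    "AnalogueResult",
    "RmsePair",
    "dissimilarity_index",
    "dissimilarity_surface",
    "rank_analogues",
    "mean_home_analysis",
    "modal_country",
    "rmse_pair",
]

_TEMP_IDX = [0, 2, 4]  # winter_tmin, interseason_tmean, summer_tmax
_VP_IDX = [1, 3, 5]


@dataclass(frozen=True)
class DissimilarityRecord:
    home_id: str
    lat: float
    lon: float
    C: float


@dataclass(frozen=True)
class RmsePair:
    home_id: str
    lat: Optional[float]
    lon: Optional[float]
    rmse_temperature: float
    rmse_vapour_pressure: float


@dataclass
class AnalogueResult:
    """Ranked climate analogues of one focal profile.

    ``ranked`` holds every cell sorted by ascending C (ties by lat, lon);
    ``top_n`` is its head.  The mean/SE summarize C over the top-n cells
    (SE = sample SD / sqrt(n)); the modal country is the most frequent
    country label among them.
    """

    home_id: str
    ranked: pd.DataFrame
    top_n: pd.DataFrame
    nearest: DissimilarityRecord
    nearest_country: str
    top_n_mean_C: float
    top_n_se_C: float
    top_n_modal_country: str
    least_similar: DissimilarityRecord = field(default=None)  # type: ignore[assignment]


def _validate(h: np.ndarray, g: np.ndarray, s: np.ndarray) -> None:
    for name, arr in (("h", h), ("g", g), ("s", s)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in {name}: {arr}")
    if np.any(s <= 0):
        raise ValueError(f"all scales must be > 0, got {s}")


def dissimilarity_index(
    h: SeasonalProfile,
    g: SeasonalProfile,
    s: VariableScale,
    sqrt_mode: bool = True,
) -> float:
    """Standardized Euclidean climate dissimilarity between two profiles."""
    ha, ga, sa = h.as_array(), g.as_array(), s.as_array()
    _validate(ha, ga, sa)
    total = float(np.sum((ga - ha) ** 2 / sa**2))
    return float(np.sqrt(total)) if sqrt_mode else total


def dissimilarity_surface(
    h: SeasonalProfile,
    s: VariableScale,
    cells: pd.DataFrame,
    sqrt_mode: bool = True,
) -> pd.DataFrame:
    """C for every cell: frame with columns lat, lon, C (one row per cell).

    ``cells`` is a profile frame as from
    :func:`climalogue.global_grid.cell_profiles` — indexed by (lat, lon)
    with the six profile columns.
    """
    if cells.empty:
        raise ValueError("empty cell set")
    ha, sa = h.as_array(), s.as_array()
    G = cells[list(PROFILE_FIELDS)].to_numpy(dtype=float)
    _validate(ha, G, sa)
    total = np.sum((G - ha[None, :]) ** 2 / sa[None, :] ** 2, axis=1)
    C = np.sqrt(total) if sqrt_mode else total
    out = pd.DataFrame(
        {
            "lat": cells.index.get_level_values("lat").to_numpy(float),
            "lon": cells.index.get_level_values("lon").to_numpy(float),
            "C": C,
        }
    )
    return out


def rank_analogues(
    home_profile: SeasonalProfile,
    s: VariableScale,
    cells: pd.DataFrame,
    n: int = 100,
    sqrt_mode: bool = True,
    countries: Optional[pd.Series] = None,
    home_id: str = "home",
) -> AnalogueResult:
    """Exhaustively rank all grid cells by dissimilarity to one profile.

    ``countries``, when given, is the per-cell label series from
    :func:`climalogue.global_grid.assign_country` (indexed like ``cells``);
    otherwise every cell is "unassigned".
    """
    if n > len(cells):
        raise ValueError(f"top-n {n} exceeds number of cells {len(cells)}")
    surface = dissimilarity_surface(home_profile, s, cells, sqrt_mode)
    if countries is not None:
        surface["country"] = countries.to_numpy()
    else:
        surface["country"] = "unassigned"
    ranked = surface.sort_values(["C", "lat", "lon"], kind="mergesort").reset_index(drop=True)
    top = ranked.head(n)

    nearest_row = ranked.iloc[0]
    worst_row = ranked.iloc[-1]
    c_top = top["C"].to_numpy()
    mean_c = float(np.mean(c_top))
    se_c = float(np.std(c_top, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return AnalogueResult(
        home_id=home_id,
        ranked=ranked,
        top_n=top,
        nearest=DissimilarityRecord(
            home_id, float(nearest_row["lat"]), float(nearest_row["lon"]), float(nearest_row["C"])
        ),
        nearest_country=str(nearest_row["country"]),
        top_n_mean_C=mean_c,
        top_n_se_C=se_c,
        top_n_modal_country=modal_country(top["country"]),
        least_similar=DissimilarityRecord(
            home_id, float(worst_row["lat"]), float(worst_row["lon"]), float(worst_row["C"])
        ),
    )


def mean_home_analysis(
    home_profiles: pd.DataFrame,
    cells: pd.DataFrame,
    n: int = 100,
    sqrt_mode: bool = True,
    countries: Optional[pd.Series] = None,
    floor: float = 0.1,
) -> AnalogueResult:
    """Analogues of the mean focal climate across homes.

    The focal profile is the variable-wise mean of the per-home profiles
    (frame with the six profile columns, one row per home); the scales are
    the across-home standard deviations of each variable.  The full
    per-cell C surface is available as ``result.ranked``.
    """
    from .climate_variables import indoor_scales

    if len(home_profiles) < 2:
        raise ValueError("mean-home analysis needs at least 2 homes (across-home SD)")
    h = SeasonalProfile.from_array(
        home_profiles[list(PROFILE_FIELDS)].mean(axis=0).to_numpy()
    )
    s = indoor_scales(home_profiles, mode="across_homes", floor=floor)
    return rank_analogues(
        h, s, cells, n=n, sqrt_mode=sqrt_mode, countries=countries, home_id="mean_home"
    )


def modal_country(labels: Sequence[str]) -> str:
    """Most frequent country label; ties broken alphabetically.

    "unassigned" never wins a tie against a real country (it can still be
    the answer when it strictly dominates).
    """
    counts = pd.Series(list(labels)).value_counts()
    if counts.empty:
        return "unassigned"
    best = counts.max()
    candidates = sorted(counts[counts == best].index)
    if len(candidates) > 1:
        real = [c for c in candidates if c != "unassigned"]
        if real:
            candidates = real
        logger.warning("modal-country tie among %s; choosing %r", candidates, candidates[0])
    return candidates[0]


def rmse_pair(
    h: SeasonalProfile, g: SeasonalProfile, home_id: str = "home", lat=None, lon=None
) -> RmsePair:
    """Unstandardized RMSE between two profiles, split by physical variable.

    Temperature RMSE pools the three temperature variables (winter minimum,
    interseason mean, summer maximum); vapour-pressure RMSE pools the three
    seasonal vapour pressures.  Units are native (degC, hPa).
    """
    diff = g.as_array() - h.as_array()
    rmse_t = float(np.sqrt(np.mean(diff[_TEMP_IDX] ** 2)))
    rmse_v = float(np.sqrt(np.mean(diff[_VP_IDX] ** 2)))
    return RmsePair(home_id, lat, lon, rmse_t, rmse_v)
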
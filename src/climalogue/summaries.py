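"""Descriptive statistics across homes and indoor~outdoor regressions.

Two views of the retained homes: (1) per-variable descriptives (min, max,
mean, standard error of the mean) of the six seasonal profile variables
across homes, the numbers behind a by-season boxplot; (2) ordinary
least-squares regressions of indoor on outdoor climate, fitted per season
on pooled month-home pairs (every retained home contributes each of its
months in the season), separately for monthly mean temperature and monthly
mean vapour pressure.  Spring and autumn pairs are pooled into one model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .climate_variables import PROFILE_FIELDS, season_of

__all__ = [
    "RegressionResult",
    "seasonal_descriptives",
    "ols_indoor_outdoor",
    "indoor_outdoor_pairs",
    "regression_table",
]


@dataclass(frozen=True)
class RegressionResult:
    season: str
    variable: str
    slope: float
    slope_se: float
    t_value: float
    p_value: float
    adj_r2: float
    df_residual: int


def seasonal_descriptives(profiles: pd.DataFrame) -> pd.DataFrame:
    """Across-home descriptives of each seasonal profile variable.

    ``profiles`` has one row per home and the six profile columns.  Returns
    one row per variable with min, max, mean and SE of the mean
    (sample SD / sqrt(n_homes)), all in native units.
    """
    if len(profiles) < 2:
        raise ValueError("descriptives need at least 2 homes")
    rows = []
    n = len(profiles)
    for var in PROFILE_FIELDS:
        vals = profiles[var].to_numpy(dtype=float)
        rows.append(
            {
                "variable": var,
                "min": float(vals.min()),
                "max": float(vals.max()),
                "mean": float(vals.mean()),
                "se_mean": float(np.std(vals, ddof=1) / np.sqrt(n)),
                "n_homes": n,
            }
        )
    return pd.DataFrame(rows)


def ols_indoor_outdoor(pairs: pd.DataFrame, season: str, variable: str) -> RegressionResult:
    """OLS of indoor on outdoor values (with intercept) for one season/variable.

    ``pairs`` needs ``indoor`` and ``outdoor`` columns, one row per pooled
    month-home observation.  Indoor is the response.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 month-home pairs")
    x = pairs["outdoor"].to_numpy(dtype=float)
    y = pairs["indoor"].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError("outdoor predictor has zero variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        season=season,
        variable=variable,
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        t_value=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        adj_r2=float(fit.rsquared_adj),
        df_residual=int(fit.df_resid),
    )


def indoor_outdoor_pairs(
    indoor_months: pd.DataFrame,
    outdoor_months: pd.DataFrame,
    hemisphere: str = "N",
) -> pd.DataFrame:
    """Month-matched indoor/outdoor values for one home.

    Joins the home's indoor and outdoor monthly frames on (year, month) and
    returns long rows (season, variable, indoor, outdoor) for monthly mean
    temperature and vapour pressure.  Spring and autumn are labelled with
    their own season here; pooling happens in :func:`regression_table`.
    """
    merged = indoor_months.merge(
        outdoor_months, on=["year", "month"], suffixes=("_in", "_out")
    )
    rows = []
    for _, r in merged.iterrows():
        season = season_of(int(r["month"]), hemisphere)
        rows.append(
            {"season": season, "variable": "temperature",
             "indoor": r["t_mean_in"], "outdoor": r["t_mean_out"]}
        )
        rows.append(
            {"season": season, "variable": "vapour_pressure",
             "indoor": r["vp_mean_in"], "outdoor": r["vp_mean_out"]}
        )
    return pd.DataFrame(rows)


def regression_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """By-season OLS table over pooled month-home pairs from all homes.

    ``pairs`` is the concatenation of :func:`indoor_outdoor_pairs` over
    homes.  Spring and autumn are pooled into "spring/autumn".  Returns one
    row per (season, variable) with slope, SE, t, p, adjusted R^2 and
    residual degrees of freedom.
    """
    p = pairs.copy()
    p["season"] = p["season"].replace({"spring": "spring/autumn", "autumn": "spring/autumn"})
    rows = []
    for (season, variable), grp in p.groupby(["season", "variable"], sort=False):
        res = ols_indoor_outdoor(grp, season, variable)
        rows.append(res.__dict__)
    order = {"winter": 0, "spring/autumn": 1, "summer": 2}
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["season", "variable"], key=lambda s: s.map(order).fillna(s)
    ).reset_index(drop=True)
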
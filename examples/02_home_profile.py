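"""From an hourly logger series to a six-variable seasonal profile.

Generates one synthetic thermostat-controlled home spanning a full year,
applies the season-coverage quality check, collapses hours to months, and
builds the seasonal profile plus the within-home variability scales that
standardize the dissimilarity index.
"""

from climalogue import (
    HomeGeneratorConfig,
    generate_home_series,
    indoor_scales,
    monthly_summaries,
    qc_season_coverage,
    seasonal_profile,
)
from climalogue.climate_variables import PROFILE_FIELDS

home = generate_home_series(HomeGeneratorConfig(seed=42, n_homes=1))[0]
report = qc_season_coverage(home)
print(f"{home.home_id}: seasons covered = {sorted(report.seasons_present)}, retained = {report.retained}")

months = monthly_summaries(home.indoor)
print(f"\n{len(months)} monthly climate rows; first three:")
print(months.head(3).to_string(index=False))

profile = seasonal_profile(months, home.hemisphere)
scales = indoor_scales(months, hemisphere=home.hemisphere)
print("\nseasonal profile (and within-home monthly SD used as its scale):")
for name, value, s in zip(PROFILE_FIELDS, profile.as_array(), scales.as_array()):
    unit = "hPa" if name.endswith("_vp") else "C"
    print(f"  {name:18s} {value:7.2f} {unit:3s}  (scale {s:5.2f})")
print("\nwinter_tmin/summer_tmax are means of monthly mean-daily extrema;")
print("the interseason values pool spring and autumn into one number.")
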
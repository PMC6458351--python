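# climalogue

**Where on Earth does an indoor climate occur outdoors?**

Homes are climate-controlled to comfort, not to the weather outside. That
raises a quantifiable question: for a given home's year-round indoor
temperature and humidity, which outdoor locations on the planet have the
most similar climate? `climalogue` answers it for anyone with hourly
indoor logger data (iButton-style temperature/relative-humidity exports)
and a gridded monthly climatology: ecologists studying the indoor biome
and the species pre-adapted to it, building scientists characterizing
achieved (rather than prescribed) indoor climates, and anyone curious
which geography their thermostat is emulating.

## The method

Every climate record — a home's logger series or a grid cell's monthly
climatology — is reduced to a six-variable seasonal profile:

| season | variables |
|---|---|
| winter (DJF in the north, JJA in the south) | mean daily-minimum temperature, mean vapour pressure |
| spring/autumn (pooled) | mean temperature, mean vapour pressure |
| summer | mean daily-maximum temperature, mean vapour pressure |

Logger relative humidity is converted to vapour pressure (hPa) per hourly
observation with the August–Roche–Magnus formula
*e*ₛ(*T*) = 6.1094 · exp(17.625 *T* / (*T* + 243.04)), so homes and grids
share units. The dissimilarity between a home profile **h** and a cell
profile **g** is a standardized Euclidean distance

&nbsp;&nbsp;&nbsp;&nbsp;*C* = √( Σₖ (*g*ₖ − *h*ₖ)² / *S*ₖ² ),&nbsp;&nbsp;k = 1…6,

where *S*ₖ is the standard deviation of variable *k* in the focal indoor
record (within-home monthly SD per home, across-home SD for the mean-home
analysis). *C* = 0 means an exact outdoor match; ranking every terrestrial
cell by *C* yields each home's nearest climate analogue, its 100 most
similar cells, and the countries they fall in (point-in-polygon on cell
centres). Companion root-mean-square errors report unstandardized
temperature and vapour-pressure mismatch in native units.

The package also reproduces the population-level summaries: across-home
descriptives of the six variables and by-season OLS regressions of indoor
on outdoor monthly climate (pooled month-home pairs), which measure how
far indoor climate has been decoupled from the weather outside.

## Worked example

A built-in generator produces study-shaped synthetic inputs (hourly
thermostat-like homes, half-degree grids with latitudinal gradients and
hemisphere-flipped seasonality), so the whole pipeline runs with no
downloads. Planting a cell whose outdoor climate equals a home's indoor
profile gives a ground-truth analogue:

```sh
python examples/03_rank_analogues.py
```

```
grid cells scanned: 800
nearest analogue:   (3.25, -1.75) in Westland, C = 0.0000
top-100 mean C:     38.572 (SE 0.414), modal country Westland
least similar cell: (0.25, 4.75), C = 87.503
```

The planted cell comes back as the rank-1 analogue with *C* = 0 — the scan
found the one outdoor location whose climate exactly matches the home —
while the least similar cell (hot, humid equatorial interior vs a
thermostat-tight home) scores far higher. `examples/01–04` walk through
each capability: the vapour-pressure conversion, a single home's profile
and scales, analogue ranking, and the mean-home surface with descriptives
and regressions.

Real data plug in the same way: per-home logger CSVs (any column naming,
via `LoggerDialect`), a CRU-style netCDF or long-CSV monthly climatology,
and GeoJSON country polygons, either through the library
(`run_analogues(...)`) or the thin CLI:

```sh
climalogue synth homes --n-homes 5 --out work/homes
climalogue synth grid --format nc --out work
climalogue analogues --homes work/homes/homes.csv --grid work/grid.nc \
    --countries work/countries.geojson --top-n 100 --out results/
```

Outputs: a QC report (which homes cover winter, summer and a shoulder
season), per-home profiles, a per-home analogue table (nearest cell and
country, top-100 mean ± SE, modal country), the full mean-home *C*
surface, seasonal descriptives, and the by-season regression table.

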
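import numpy as np
import pandas as pd
import pytest

from climalogue import (
    GridGeneratorConfig,
    HomeGeneratorConfig,
    cell_profiles,
    generate_grid,
    generate_home_series,
)


@pytest.fixture(scope="session")
def small_homes():
    """Three synthetic homes spanning the full study window."""
    return generate_home_series(HomeGeneratorConfig(seed=7, n_homes=3))


@pytest.fixture(scope="session")
def small_grid():
    """Noise-free 20x20-cell tropical grid straddling the equator."""
    cfg = GridGeneratorConfig(
        seed=0, lat_min=-4.75, lat_max=4.75, lon_min=-4.75, lon_max=4.75
    )
    return generate_grid(cfg)


@pytest.fixture(scope="session")
def small_cells(small_grid):
    return cell_profiles(small_grid)


@pytest.fixture()
def constant_month():
    """One month of hourly constant conditions (T=20, RH=50)."""
    ts = pd.date_range("2013-06-01", "2013-06-30 23:00", freq="h")
    return pd.DataFrame(
        {
            "timestamp": ts,
            "temperature": np.full(len(ts), 20.0),
            "relative_humidity": np.full(len(ts), 50.0),
        }
    )
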
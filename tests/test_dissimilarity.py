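"""Dissimilarity index, analogue ranking against a naive oracle, RMSE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from climalogue import dissimilarity as dis
from climalogue import synthetic_data as sd
from climalogue.climate_variables import PROFILE_FIELDS, SeasonalProfile, VariableScale
from climalogue.global_grid import cell_profiles

UNIT_SCALE = VariableScale.from_array(np.ones(6))


def profile(*vals):
    return SeasonalProfile.from_array(vals)


finite_profiles = st.tuples(
    st.floats(-20, 10), st.floats(0, 20), st.floats(-5, 25),
    st.floats(0, 25), st.floats(0, 40), st.floats(0, 30),
)
scales6 = st.tuples(*[st.floats(0.1, 10)] * 6)


class TestIndex:
    def test_identity_is_zero(self):
        h = profile(20, 10, 22, 12, 27, 16)
        assert dis.dissimilarity_index(h, h, UNIT_SCALE) == 0.0

    def test_one_scale_unit_deviation_gives_one_in_both_modes(self):
        h = profile(20, 10, 22, 12, 27, 16)
        g = profile(20, 10, 22, 12, 27 + 1.5, 16)
        s = VariableScale.from_array([1, 1, 1, 1, 1.5, 1])
        assert dis.dissimilarity_index(h, g, s, sqrt_mode=True) == pytest.approx(1.0)
        assert dis.dissimilarity_index(h, g, s, sqrt_mode=False) == pytest.approx(1.0)

    def test_hand_example(self):
        h = profile(20, 10, 22, 12, 27, 16)
        g = profile(18, 9, 22, 12, 30, 16)
        s = VariableScale.from_array([1, 1, 1, 1, 1.5, 1])
        # (2/1)^2 + (1/1)^2 + (3/1.5)^2 = 9
        assert dis.dissimilarity_index(h, g, s) == pytest.approx(3.0)
        assert dis.dissimilarity_index(h, g, s, sqrt_mode=False) == pytest.approx(9.0)

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(h=finite_profiles, g=finite_profiles, s=scales6, factor=st.floats(0.1, 50))
    def test_scale_invariance(self, h, g, s, factor):
        """Rescaling one variable jointly in h, g and s leaves C unchanged."""
        base = dis.dissimilarity_index(
            profile(*h), profile(*g), VariableScale.from_array(s)
        )
        h2, g2, s2 = list(h), list(g), list(s)
        h2[2] *= factor
        g2[2] *= factor
        s2[2] *= factor
        scaled = dis.dissimilarity_index(
            profile(*h2), profile(*g2), VariableScale.from_array(s2)
        )
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(h=finite_profiles, g=finite_profiles, s=scales6, extra=st.floats(0, 30))
    def test_monotone_in_single_coordinate_deviation(self, h, g, s, extra):
        hp, gp = profile(*h), profile(*g)
        sv = VariableScale.from_array(s)
        base = dis.dissimilarity_index(hp, gp, sv)
        g2 = list(g)
        g2[5] = h[5] + (g[5] - h[5]) + np.copysign(extra, g[5] - h[5] or 1.0)
        widened = dis.dissimilarity_index(hp, profile(*g2), sv)
        assert widened >= base - 1e-12

    def test_non_finite_rejected(self):
        h = profile(20, 10, 22, 12, 27, 16)
        bad = pd.DataFrame(
            [[np.inf, 1, 1, 1, 1, 1]], columns=list(PROFILE_FIELDS),
            index=pd.MultiIndex.from_tuples([(0.25, 0.25)], names=["lat", "lon"]),
        )
        with pytest.raises(ValueError):
            dis.dissimilarity_surface(h, UNIT_SCALE, bad)


def naive_rank(h, s, cells, sqrt_mode=True):
    """Independent re-implementation: per-cell loop + stdlib sort."""
    records = []
    for (lat, lon), row in cells.iterrows():
        total = sum(
            (row[f] - getattr(h, f)) ** 2 / s.as_array()[k] ** 2
            for k, f in enumerate(PROFILE_FIELDS)
        )
        c = total**0.5 if sqrt_mode else total
        records.append((c, lat, lon))
    records.sort()
    return records


class TestRanking:
    def test_matches_naive_oracle(self, small_cells):
        h = SeasonalProfile.from_array(small_cells.iloc[37].to_numpy() + 0.3)
        s = VariableScale.from_array([1.0, 0.5, 2.0, 0.8, 1.5, 0.4])
        for sqrt_mode in (True, False):
            result = dis.rank_analogues(h, s, small_cells, n=25, sqrt_mode=sqrt_mode)
            oracle = naive_rank(h, s, small_cells, sqrt_mode)
            got = list(
                result.ranked[["C", "lat", "lon"]].itertuples(index=False, name=None)
            )
            assert len(got) == len(oracle)
            for (c1, la1, lo1), (c2, la2, lo2) in zip(got, oracle):
                assert c1 == pytest.approx(c2, abs=1e-9)
                assert (la1, lo1) == (la2, lo2)

    def test_planted_analogue_is_rank_one(self, small_grid):
        target = profile(18, 9, 21, 12, 28, 15)
        planted = sd.plant_analogue(small_grid, target, at=(2.25, -3.75))
        cells = cell_profiles(planted)
        result = dis.rank_analogues(target, UNIT_SCALE, cells, n=5)
        assert (result.nearest.lat, result.nearest.lon) == (2.25, -3.75)
        assert result.nearest.C < 1e-9

    def test_two_planted_cells_tie_broken_by_lat_lon(self, small_grid):
        target = profile(18, 9, 21, 12, 28, 15)
        planted = sd.plant_analogue(small_grid, target, at=(2.25, -3.75))
        planted = sd.plant_analogue(planted, target, at=(-1.25, 0.25))
        result = dis.rank_analogues(target, UNIT_SCALE, cell_profiles(planted), n=5)
        top2 = result.top_n.iloc[:2]
        assert list(top2["C"]) == pytest.approx([0.0, 0.0], abs=1e-12)
        assert (top2.iloc[0]["lat"], top2.iloc[0]["lon"]) == (-1.25, 0.25)

    def test_top_n_se_is_sd_over_sqrt_n(self, small_cells):
        h = SeasonalProfile.from_array(small_cells.iloc[0].to_numpy())
        result = dis.rank_analogues(h, UNIT_SCALE, small_cells, n=50)
        c = result.top_n["C"].to_numpy()
        assert result.top_n_se_C == pytest.approx(np.std(c, ddof=1) / np.sqrt(50))
        assert result.top_n_mean_C == pytest.approx(c.mean())
        assert (result.nearest.lat, result.nearest.lon) == (
            result.top_n.iloc[0]["lat"], result.top_n.iloc[0]["lon"],
        )

    def test_empty_cells_raise(self):
        h = profile(18, 9, 21, 12, 28, 15)
        empty = pd.DataFrame(
            columns=list(PROFILE_FIELDS),
            index=pd.MultiIndex.from_arrays([[], []], names=["lat", "lon"]),
        )
        with pytest.raises(ValueError):
            dis.rank_analogues(h, UNIT_SCALE, empty, n=0)

    def test_sqrt_modes_rank_identically(self, small_cells):
        h = SeasonalProfile.from_array(small_cells.iloc[11].to_numpy() + 1.0)
        on = dis.rank_analogues(h, UNIT_SCALE, small_cells, n=10, sqrt_mode=True)
        off = dis.rank_analogues(h, UNIT_SCALE, small_cells, n=10, sqrt_mode=False)
        assert on.ranked[["lat", "lon"]].equals(off.ranked[["lat", "lon"]])
        assert np.allclose(off.ranked["C"], on.ranked["C"] ** 2)


class TestMeanHome:
    def test_identical_homes_with_planted_common_profile(self, small_grid):
        target = profile(18, 9, 21, 12, 28, 15)
        planted = sd.plant_analogue(small_grid, target, at=(0.25, 0.25))
        cells = cell_profiles(planted)
        profiles = pd.DataFrame(
            [target.as_array()] * 3, columns=list(PROFILE_FIELDS)
        )
        result = dis.mean_home_analysis(profiles, cells, n=5)
        assert result.nearest.C < 1e-9
        assert (result.nearest.lat, result.nearest.lon) == (0.25, 0.25)
        assert result.least_similar.C >= result.nearest.C

    def test_surface_unimodal_along_latitudinal_gradient(self):
        """C along one meridian of a monotone-gradient grid dips once."""
        cfg = sd.GridGeneratorConfig(
            lat_min=0.25, lat_max=40.25, lon_min=0.25, lon_max=0.75,
            base_amplitude=0.0, amplitude_per_degree=0.0,
        )
        cells = cell_profiles(sd.generate_grid(cfg))
        mid = cells.loc[(20.25, 0.25)]
        profiles = pd.DataFrame(
            [mid.to_numpy() + d for d in (-0.05, 0.0, 0.05)],
            columns=list(PROFILE_FIELDS),
        )
        result = dis.mean_home_analysis(profiles, cells, n=3)
        lane = result.ranked[result.ranked["lon"] == 0.25].sort_values("lat")
        c = lane["C"].to_numpy()
        k = int(np.argmin(c))
        assert np.all(np.diff(c[: k + 1]) <= 1e-9) and np.all(np.diff(c[k:]) >= -1e-9)

    def test_fewer_than_two_homes_raise(self, small_cells):
        profiles = pd.DataFrame([small_cells.iloc[0].to_numpy()], columns=list(PROFILE_FIELDS))
        with pytest.raises(ValueError):
            dis.mean_home_analysis(profiles, small_cells)


class TestModalCountry:
    def test_majority_wins(self):
        assert dis.modal_country(["A"] * 60 + ["B"] * 40) == "A"

    def test_tie_broken_alphabetically(self):
        assert dis.modal_country(["B"] * 50 + ["A"] * 50) == "A"

    def test_unassigned_never_wins_a_tie(self):
        assert dis.modal_country(["unassigned"] * 50 + ["Z"] * 50) == "Z"

    def test_unassigned_can_strictly_dominate(self):
        assert dis.modal_country(["unassigned"] * 3 + ["Z"]) == "unassigned"


class TestRmse:
    def test_identity(self):
        h = profile(10, 8, 22, 12, 27, 16)
        pair = dis.rmse_pair(h, h)
        assert pair.rmse_temperature == 0.0 and pair.rmse_vapour_pressure == 0.0

    def test_constant_temperature_offset(self):
        h = profile(10, 8, 22, 12, 27, 16)
        g = profile(12, 8, 24, 12, 29, 16)
        pair = dis.rmse_pair(h, g)
        assert pair.rmse_temperature == pytest.approx(2.0)
        assert pair.rmse_vapour_pressure == 0.0

    def test_hand_example(self):
        h = profile(10, 8, 22, 12, 27, 16)
        g = profile(12, 8, 22, 12, 31, 16)
        pair = dis.rmse_pair(h, g)
        assert pair.rmse_temperature == pytest.approx(np.sqrt(20 / 3))  # ~2.582
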
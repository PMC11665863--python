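"""Range limits from occurrence clouds and within-range positions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fishwarm import assign_positions, position_in_range, range_size_km, trim_and_limit


def cloud(species, lats):
    return pd.DataFrame(
        {"species": species, "latitude": np.asarray(lats, float), "longitude": 0.0}
    )


class TestTrimAndLimit:
    def test_percentile_limits_on_integer_grid(self):
        # 101 points at 0..100: interpolated 1st/99th percentiles are 1.0/99.0
        # (hypothetical latitudes to pin the quantile convention)
        occ = cloud("sp", np.arange(0, 101) * 0.9)  # keep under 90
        out = trim_and_limit(occ)
        assert out.loc[0, "equatorward_limit"] == pytest.approx(0.9, abs=1e-9)
        assert out.loc[0, "poleward_limit"] == pytest.approx(89.1, abs=1e-9)

    def test_degenerate_single_latitude_excluded(self):
        occ = cloud("sp", np.full(50, 43.0))
        assert len(trim_and_limit(occ)) == 0

    def test_too_few_occurrences_excluded(self):
        occ = cloud("sp", np.linspace(30, 40, 5))
        assert len(trim_and_limit(occ, min_occurrences=10)) == 0

    def test_equator_spanner_split_with_equator_as_equatorward_limit(self):
        occ = cloud("sp", np.arange(-20, 31, dtype=float))
        out = trim_and_limit(occ).set_index("hemisphere")
        assert set(out.index) == {"north", "south"}
        assert out.loc["north", "equatorward_limit"] == 0.0
        assert out.loc["south", "equatorward_limit"] == 0.0
        # per-component 99th percentiles of |lat|
        north = np.arange(0, 31, dtype=float)
        south = -np.arange(-20, 1, dtype=float)
        assert out.loc["north", "poleward_limit"] == pytest.approx(
            np.quantile(north, 0.99), abs=1e-9
        )
        assert out.loc["south", "poleward_limit"] == pytest.approx(
            np.quantile(south, 0.99), abs=1e-9
        )

    def test_native_hemisphere_restricts_occurrences(self):
        lats = np.concatenate([np.linspace(35, 55, 80), np.linspace(-45, -35, 20)])
        occ = cloud("sp", lats)
        out = trim_and_limit(occ, native_hemisphere={"sp": "north"})
        assert list(out["hemisphere"]) == ["north"]
        assert out.loc[0, "equatorward_limit"] >= 35.0

    def test_trimming_never_widens_limits(self, rng):
        lats = rng.uniform(20, 60, 500)
        out = trim_and_limit(cloud("sp", lats))
        assert out.loc[0, "equatorward_limit"] >= lats.min()
        assert out.loc[0, "poleward_limit"] <= lats.max()

    def test_drop_method_removes_k_points_per_tail(self):
        lats = np.linspace(30, 50, 200)
        out = trim_and_limit(cloud("sp", lats), method="drop")
        srt = np.sort(lats)
        assert out.loc[0, "equatorward_limit"] == pytest.approx(srt[2])
        assert out.loc[0, "poleward_limit"] == pytest.approx(srt[-3])

    def test_limits_converge_to_generative_band(self, rng):
        lats = rng.uniform(30.0, 50.0, 10_000)
        out = trim_and_limit(cloud("sp", lats))
        assert abs(out.loc[0, "equatorward_limit"] - 30.0) < 0.5
        assert abs(out.loc[0, "poleward_limit"] - 50.0) < 0.5


class TestPositionInRange:
    @pytest.mark.parametrize(
        "lat, eq, pole, expected",
        [
            (20.0, 20.0, 60.0, 0.0),   # equatorward endpoint
            (60.0, 20.0, 60.0, 1.0),   # poleward endpoint
            (30.0, 20.0, 60.0, 0.25),  # formula arithmetic
            (-35.0, 10.0, 50.0, 0.625),  # southern site on absolute latitude
        ],
    )
    def test_formula_cases(self, lat, eq, pole, expected):
        pos, clamped = position_in_range(lat, eq, pole)
        assert pos == pytest.approx(expected, abs=1e-12)
        assert not clamped

    def test_out_of_range_clamped_and_flagged(self):
        pos, clamped = position_in_range(65.0, 20.0, 60.0)
        assert pos == 1.0 and clamped
        pos, clamped = position_in_range(15.0, 20.0, 60.0, clamp=False)
        assert pos == pytest.approx(-0.125) and clamped

    def test_zero_width_range_rejected(self):
        with pytest.raises(ValueError):
            position_in_range(30.0, 40.0, 40.0)


class TestRangeSizeKm:
    def test_conversion_constant(self):
        assert range_size_km(10.0) == pytest.approx(1113.2)
        assert range_size_km(0.0) == 0.0

    @given(st.floats(min_value=0, max_value=90), st.floats(min_value=0, max_value=90))
    @settings(max_examples=50, deadline=None)
    def test_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert range_size_km(hi) >= range_size_km(lo)


class TestHemisphereSymmetry:
    def test_reflection_invariance(self, rng):
        """Negating every latitude (occurrences and sites) leaves positions
        unchanged: the statistic lives on absolute latitude."""
        lats = rng.uniform(25, 55, 400)
        occ_n = cloud("sp", lats)
        occ_s = cloud("sp", -lats)
        pops_n = pd.DataFrame(
            {"time_series_id": ["t1"], "species": ["sp"], "latitude": [40.0]}
        )
        pops_s = pops_n.assign(latitude=-pops_n["latitude"])
        pos_n = assign_positions(pops_n, trim_and_limit(occ_n))
        pos_s = assign_positions(pops_s, trim_and_limit(occ_s))
        assert pos_n.loc[0, "position"] == pytest.approx(pos_s.loc[0, "position"], abs=1e-12)


class TestAssignPositions:
    def test_equator_spanner_resolved_by_site_hemisphere(self):
        occ = cloud("sp", np.arange(-20, 31, dtype=float))
        rngs = trim_and_limit(occ)
        pops = pd.DataFrame(
            {
                "time_series_id": ["n", "s"],
                "species": ["sp", "sp"],
                "latitude": [10.0, -10.0],
            }
        )
        out = assign_positions(pops, rngs).set_index("time_series_id")
        assert out.loc["n", "hemisphere"] == "north"
        assert out.loc["s", "hemisphere"] == "south"
        assert 0 < out.loc["n", "position"] < 1

    def test_unmatched_species_dropped(self):
        rngs = trim_and_limit(cloud("sp", np.linspace(30, 50, 100)))
        pops = pd.DataFrame(
            {
                "time_series_id": ["a", "b"],
                "species": ["sp", "sp"],
                "latitude": [40.0, -40.0],  # no southern component exists
            }
        )
        out = assign_positions(pops, rngs)
        assert list(out["time_series_id"]) == ["a"]
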
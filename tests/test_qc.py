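"""Occurrence cleaning cascade: boundary behaviour, flag bookkeeping,
thinning and the minimum-sample rule."""

import numpy as np
import pandas as pd
import pytest

from shaderange.grids import CLIMATIC, GridSpec
from shaderange.qc import (
    apply_min_sample,
    filter_coordinates,
    filter_land,
    filter_marginal_climate,
    filter_source,
    filter_year,
    retained_mask,
    run_qc,
    thin_to_grid,
)
from shaderange.synthetic import (
    Contamination,
    LayerSpec,
    NicheResponse,
    SpeciesNicheTruth,
    generate_env_stack,
    sample_occurrences,
)


def table(rows, **extra):
    base = pd.DataFrame(rows, columns=["species", "lon", "lat", "year", "source"])
    for k, v in extra.items():
        base[k] = v
    return base


class TestFilterCoordinates:
    @pytest.mark.parametrize("lon,lat,flagged", [
        (np.nan, 6.8, True),     # missing longitude
        (-5.2, 91.0, True),      # latitude out of range
        (181.0, 0.0, True),
        (-5.2, 6.8, False),      # valid West African coordinate
    ])
    def test_boundary_cases(self, lon, lat, flagged):
        out = filter_coordinates(table([("sp", lon, lat, 2001, "survey")]))
        assert bool(out.loc[0, "flag_bad_coord"]) is flagged

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            filter_coordinates(table([]))

    def test_row_count_conserved(self):
        out = filter_coordinates(table([("a", np.nan, 0, 2000, "s"),
                                        ("b", 0, 0, 2000, "s")]))
        assert len(out) == 2


class TestFilterLand:
    def test_ocean_and_land_cells(self, env_small):
        oc = tuple(a[0] for a in np.where(env_small.nodata_mask))
        la = tuple(a[0] for a in np.where(env_small.land_mask))
        lon_o, lat_o = env_small.grid.cell_center(*oc)
        lon_l, lat_l = env_small.grid.cell_center(*la)
        out = filter_land(filter_coordinates(table([
            ("sp", float(lon_o), float(lat_o), 2000, "s"),
            ("sp", float(lon_l), float(lat_l), 2000, "s"),
            ("sp", 100.0, 50.0, 2000, "s"),  # off the study grid
        ])), env_small)
        assert out["flag_off_land"].tolist() == [True, False, True]

    def test_injected_ocean_points_exactly_flagged(self, env_small, truth_two_layer):
        occ = sample_occurrences(truth_two_layer, env_small, n_clean=50,
                                 contamination=Contamination(n_ocean=5), seed=2)
        out = filter_land(filter_coordinates(occ), env_small)
        assert out["flag_off_land"].sum() == 5
        assert (out.loc[out["flag_off_land"], "truth"] == "ocean").all()


class TestFilterYear:
    @pytest.mark.parametrize("year,flagged", [
        (1968, True),    # strictly before the baseline
        (1969, False),   # the baseline year itself is retained
        (np.nan, True),  # undated records are flagged by default
    ])
    def test_baseline_boundary(self, year, flagged):
        out = filter_year(table([("sp", 0.0, 0.0, year, "s")]))
        assert bool(out.loc[0, "flag_pre_baseline"]) is flagged

    def test_missing_year_configurable(self):
        out = filter_year(table([("sp", 0.0, 0.0, np.nan, "s")]), flag_missing=False)
        assert not out.loc[0, "flag_pre_baseline"]


class TestFilterSource:
    def test_blacklist(self):
        out = filter_source(table([("sp", 0, 0, 2000, "fossil"),
                                   ("sp", 0, 0, 2000, "unknown"),
                                   ("sp", 0, 0, 2000, "survey")]))
        assert out["flag_unknown_source"].tolist() == [True, True, False]


@pytest.fixture(scope="module")
def gradient_env():
    grid = GridSpec.from_bounds(0, 0, 5, 5, resolution=0.1)
    env = generate_env_stack(grid, [LayerSpec("clim", CLIMATIC, sd=0.0,
                                              smoothing=0.0)])
    lon, _ = grid.center_mesh()
    env.layers["clim"] = lon.copy()  # strictly increasing west -> east
    return env


class TestFilterMarginalClimate:
    def test_unique_maximum_is_flagged(self, gradient_env):
        grid = gradient_env.grid
        lons = grid.x_centers()[5:104]  # 99 interior cells
        rows = [("sp", float(l), grid.y_centers()[10], 2000, "s") for l in lons]
        rows.append(("sp", float(grid.x_centers()[-1]), grid.y_centers()[10], 2000, "s"))
        out = filter_marginal_climate(table(rows), gradient_env, ["clim"])
        assert bool(out.loc[len(rows) - 1, "flag_marginal_climate"])

    def test_identical_climate_flags_nothing(self, gradient_env):
        grid = gradient_env.grid
        lon = float(grid.x_centers()[10])
        rows = [("sp", lon, float(lat), 2000, "s") for lat in grid.y_centers()[:30]]
        out = filter_marginal_climate(table(rows), gradient_env, ["clim"])
        assert not out["flag_marginal_climate"].any()

    def test_zero_tail_flags_nothing(self, gradient_env):
        grid = gradient_env.grid
        rows = [("sp", float(l), grid.y_centers()[0], 2000, "s")
                for l in grid.x_centers()[:30]]
        out = filter_marginal_climate(table(rows), gradient_env, ["clim"],
                                      tail_fraction=0.0)
        assert not out["flag_marginal_climate"].any()

    def test_quantile_oracle(self, gradient_env):
        grid = gradient_env.grid
        lons = grid.x_centers()
        rows = [("sp", float(l), grid.y_centers()[3], 2000, "s") for l in lons]
        out = filter_marginal_climate(table(rows), gradient_env, ["clim"],
                                      tail_fraction=0.10)
        vals = np.array([r[1] for r in rows])
        lo, hi = np.quantile(vals, [0.05, 0.95])
        expect = (vals < lo) | (vals > hi)
        np.testing.assert_array_equal(out["flag_marginal_climate"].to_numpy(), expect)

    def test_small_species_skipped_with_warning(self, gradient_env):
        grid = gradient_env.grid
        rows = [("sp", float(l), grid.y_centers()[0], 2000, "s")
                for l in grid.x_centers()[:5]]
        with pytest.warns(UserWarning, match="skipping"):
            out = filter_marginal_climate(table(rows), gradient_env, ["clim"])
        assert not out["flag_marginal_climate"].any()

    def test_missing_layer_rejected(self, gradient_env):
        with pytest.raises(KeyError, match="absent"):
            filter_marginal_climate(
                table([("sp", 0.05, 0.05, 2000, "s")] * 25), gradient_env, ["nope"])


class TestThinning:
    @pytest.mark.parametrize("k", list(range(2, 11)))
    def test_k_cocell_records_thin_to_one(self, grid_small, k):
        lon, lat = grid_small.cell_center(3, 3)
        rows = [("sp", float(lon) + 0.001 * i, float(lat), 2000 + i, "s")
                for i in range(k)]
        out = thin_to_grid(table(rows), grid_small)
        assert out["flag_thinned"].sum() == k - 1
        assert retained_mask(out).sum() == 1

    def test_distinct_cells_untouched(self, grid_small):
        lon0, lat0 = grid_small.cell_center(0, 0)
        lon1, lat1 = grid_small.cell_center(5, 5)
        out = thin_to_grid(table([("sp", float(lon0), float(lat0), 2000, "s"),
                                  ("sp", float(lon1), float(lat1), 2000, "s")]),
                           grid_small)
        assert not out["flag_thinned"].any()

    def test_tiebreak_most_recent_year_then_lowest_index(self, grid_small):
        lon, lat = grid_small.cell_center(2, 2)
        out = thin_to_grid(table([
            ("sp", float(lon), float(lat), 1990, "s"),
            ("sp", float(lon), float(lat), 2010, "s"),
            ("sp", float(lon), float(lat), 2010, "s"),
        ]), grid_small)
        assert out["flag_thinned"].tolist() == [True, False, True]

    def test_idempotent(self, grid_small):
        lon, lat = grid_small.cell_center(2, 2)
        t = table([("sp", float(lon), float(lat), y, "s") for y in (1990, 2000)])
        once = thin_to_grid(t, grid_small)
        twice = thin_to_grid(once, grid_small)
        assert once.equals(twice)

    def test_species_kept_separate(self, grid_small):
        lon, lat = grid_small.cell_center(2, 2)
        out = thin_to_grid(table([("a", float(lon), float(lat), 2000, "s"),
                                  ("b", float(lon), float(lat), 2000, "s")]),
                           grid_small)
        assert not out["flag_thinned"].any()


class TestMinSample:
    @pytest.mark.parametrize("n,kept", [(61, True), (60, False), (0, False)])
    def test_strict_threshold(self, n, kept):
        t = table([("sp", float(i), 0.0, 2000, "s") for i in range(n)])
        assert (("sp" in apply_min_sample(t)) is kept)

    def test_empty_input(self):
        assert apply_min_sample(table([])) == set()


class TestCascade:
    def test_full_cascade_flags_each_injected_class(self, env_small, truth_two_layer):
        cont = Contamination(n_ocean=6, n_pre_baseline=8, n_duplicates=4)
        occ = sample_occurrences(truth_two_layer, env_small, n_clean=120,
                                 contamination=cont, seed=5)
        out, kept, report = run_qc(occ, env_small, tail_fraction=0.0)
        assert len(out) == len(occ)  # no deletion, only flags
        assert out.loc[out["truth"] == "ocean", "flag_off_land"].all()
        assert out["flag_off_land"].sum() == 6
        assert out.loc[out["truth"] == "pre_baseline", "flag_pre_baseline"].all()
        assert out["flag_pre_baseline"].sum() == 8
        # each exact duplicate collides with its source: one of the pair thinned
        assert out["flag_thinned"].sum() >= 4

    def test_cascade_idempotent(self, env_small, truth_two_layer):
        occ = sample_occurrences(truth_two_layer, env_small, n_clean=100,
                                 contamination=Contamination(n_ocean=3), seed=6)
        once, _, _ = run_qc(occ, env_small)
        twice, _, _ = run_qc(once, env_small)
        pd.testing.assert_frame_equal(once, twice)

    def test_report_counts_add_up(self, env_small, truth_two_layer):
        occ = sample_occurrences(truth_two_layer, env_small, n_clean=80,
                                 contamination=Contamination(n_pre_baseline=5), seed=7)
        out, _, report = run_qc(occ, env_small)
        row = report.iloc[0]
        assert row["n_input"] == 85
        assert row["n_retained"] == retained_mask(out).sum()
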
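"""Virtual-species generators: determinism, moments, closed-form niches,
contamination bookkeeping, scenario shifts and land cover."""

import numpy as np
import pytest

from shaderange.grids import CLIMATIC, EDAPHIC, GridSpec
from shaderange.synthetic import (
    Contamination,
    LayerSpec,
    NicheResponse,
    ScenarioShift,
    SpeciesNicheTruth,
    apply_scenario,
    generate_env_stack,
    generate_land_mask,
    generate_landcover,
    sample_occurrences,
    true_suitability,
)


class TestGenerateEnvStack:
    def test_degenerate_noise_gives_constant_layer(self, grid_small):
        env = generate_env_stack(
            grid_small, [LayerSpec("flat", CLIMATIC, mean=7.5, sd=0.0, smoothing=0.0)])
        np.testing.assert_array_equal(env.layers["flat"], 7.5)

    def test_same_seed_bit_identical(self, grid_small):
        specs = [LayerSpec("a", CLIMATIC), LayerSpec("b", EDAPHIC, smoothing=0.0)]
        e1 = generate_env_stack(grid_small, specs, seed=5)
        e2 = generate_env_stack(grid_small, specs, seed=5)
        for n in ("a", "b"):
            np.testing.assert_array_equal(e1.layers[n], e2.layers[n])
        e3 = generate_env_stack(grid_small, specs, seed=6)
        assert not np.array_equal(e1.layers["a"], e3.layers["a"])

    def test_sample_moments_match_request(self):
        grid = GridSpec.from_bounds(0, 0, 100 * 2.5 / 60, 100 * 2.5 / 60)
        env = generate_env_stack(
            grid, [LayerSpec("x", CLIMATIC, mean=3.0, sd=1.0, smoothing=2.0)], seed=1)
        vals = env.layers["x"]
        assert abs(vals.std() - 1.0) < 0.1
        assert abs(vals.mean() - 3.0) < 0.1

    def test_duplicate_layer_name_rejected(self, grid_small):
        with pytest.raises(ValueError, match="duplicate"):
            generate_env_stack(grid_small,
                               [LayerSpec("a", CLIMATIC), LayerSpec("a", EDAPHIC)])


class TestTrueSuitability:
    def test_value_one_at_joint_optimum_before_rescaling(self, env_small):
        # plant the optimum at an actual land cell's values
        r, c = map(lambda a: a[0], np.where(env_small.land_mask))
        truth = SpeciesNicheTruth("sp", {
            "BIO1": NicheResponse(env_small.layers["BIO1"][r, c], 1.0),
            "BIO12": NicheResponse(env_small.layers["BIO12"][r, c], 100.0),
        })
        suit = true_suitability(truth, env_small, rescale=False)
        assert suit[r, c] == pytest.approx(1.0)

    def test_infinite_tolerance_layer_contributes_nothing(self, env_small):
        base = SpeciesNicheTruth("sp", {"BIO1": NicheResponse(26.0, 1.0)})
        padded = SpeciesNicheTruth("sp", {
            "BIO1": NicheResponse(26.0, 1.0),
            "BIO12": NicheResponse(0.0, np.inf),
        })
        np.testing.assert_array_equal(
            true_suitability(base, env_small, rescale=False),
            true_suitability(padded, env_small, rescale=False))

    def test_closed_form_product_of_gaussians(self, env_small):
        truth = SpeciesNicheTruth("sp", {
            "BIO1": NicheResponse(26.0, 1.5),
            "BIO12": NicheResponse(1800.0, 250.0),
        })
        suit = true_suitability(truth, env_small, rescale=False)
        rows, cols = np.where(env_small.land_mask)
        for r, c in zip(rows[:3], cols[:3]):
            z1 = (env_small.layers["BIO1"][r, c] - 26.0) / 1.5
            z2 = (env_small.layers["BIO12"][r, c] - 1800.0) / 250.0
            assert suit[r, c] == pytest.approx(np.exp(-0.5 * (z1**2 + z2**2)))

    def test_rescaled_mean_over_land_hits_prevalence(self, env_small, truth_two_layer):
        suit = true_suitability(truth_two_layer, env_small)
        assert np.nanmean(suit[env_small.land_mask]) == pytest.approx(
            truth_two_layer.prevalence_target, abs=1e-6)
        assert np.isnan(suit[env_small.nodata_mask]).all()

    def test_missing_layer_named_in_error(self, env_small):
        truth = SpeciesNicheTruth("sp", {"BIO99": NicheResponse(0.0, 1.0)})
        with pytest.raises(KeyError, match="BIO99"):
            true_suitability(truth, env_small)

    def test_truth_invariants(self):
        with pytest.raises(ValueError, match="prevalence"):
            SpeciesNicheTruth("sp", {"a": NicheResponse(0, 1)}, prevalence_target=1.5)
        with pytest.raises(ValueError, match="tolerance"):
            SpeciesNicheTruth("sp", {"a": NicheResponse(0, np.inf)})


class TestSampleOccurrences:
    def test_clean_sample_is_on_land_and_post_baseline(self, env_small, truth_two_layer):
        occ = sample_occurrences(truth_two_layer, env_small, n_clean=200, seed=3)
        assert (occ["truth"] == "clean").all()
        assert (occ["year"] >= 1969).all()
        r, c = env_small.grid.cell_of(occ["lon"], occ["lat"])
        assert (r >= 0).all()
        assert not env_small.nodata_mask[r, c].any()

    def test_contamination_bookkeeping_is_exact(self, env_small, truth_two_layer):
        cont = Contamination(n_ocean=5, n_pre_baseline=7, n_duplicates=3, n_marginal=4)
        occ = sample_occurrences(truth_two_layer, env_small, n_clean=100,
                                 contamination=cont, seed=9)
        counts = occ["truth"].value_counts()
        assert counts["clean"] == 100
        assert counts["ocean"] == 5
        assert counts["pre_baseline"] == 7
        assert counts["duplicate"] == 3
        assert counts["marginal"] == 4
        ocean = occ[occ["truth"] == "ocean"]
        r, c = env_small.grid.cell_of(ocean["lon"], ocean["lat"])
        assert env_small.nodata_mask[r, c].all()
        assert (occ.loc[occ["truth"] == "pre_baseline", "year"] < 1969).all()

    def test_contamination_beyond_capacity_rejected(self, env_small, truth_two_layer):
        n_ocean_cells = int(env_small.nodata_mask.sum())
        with pytest.raises(ValueError, match="ocean"):
            sample_occurrences(truth_two_layer, env_small, n_clean=10,
                               contamination=Contamination(n_ocean=n_ocean_cells + 1))

    def test_uniform_truth_occupancy_proportional_to_region_size(self, grid_small):
        # nearly flat niche => cell-uniform sampling; compare the two grid
        # halves against a binomial with p = share of land cells
        env = generate_env_stack(
            grid_small, [LayerSpec("x", CLIMATIC, mean=0, sd=1, smoothing=3)], seed=2)
        truth = SpeciesNicheTruth("sp", {"x": NicheResponse(0.0, 1e9)},
                                  prevalence_target=0.5)
        occ = sample_occurrences(truth, env, n_clean=10_000, seed=4)
        r, _ = env.grid.cell_of(occ["lon"], occ["lat"])
        split = grid_small.n_rows // 2
        p_north = (np.arange(grid_small.n_rows) < split).mean()  # all cells are land
        n_north = (r < split).sum()
        se = np.sqrt(10_000 * p_north * (1 - p_north))
        assert abs(n_north - 10_000 * p_north) < 4 * se

    def test_determinism(self, env_small, truth_two_layer):
        a = sample_occurrences(truth_two_layer, env_small, n_clean=50, seed=1)
        b = sample_occurrences(truth_two_layer, env_small, n_clean=50, seed=1)
        assert a.equals(b)


class TestApplyScenario:
    def test_identity_shift_returns_equal_stack(self, env_small):
        shift = ScenarioShift("id", offsets={"BIO1": 0.0}, factors={"BIO1": 1.0})
        out = apply_scenario(env_small, shift)
        for name in env_small.layer_names:
            np.testing.assert_array_equal(out.layers[name], env_small.layers[name])

    def test_offset_moves_mean_exactly(self, env_small):
        out = apply_scenario(env_small, ScenarioShift("w", offsets={"BIO1": 2.0}))
        land = env_small.land_mask
        assert out.layers["BIO1"][land].mean() == pytest.approx(
            env_small.layers["BIO1"][land].mean() + 2.0)

    def test_factor_scales_sd(self, env_small):
        out = apply_scenario(env_small, ScenarioShift("d", factors={"BIO18": 0.5}))
        assert out.layers["BIO18"].std() == pytest.approx(
            env_small.layers["BIO18"].std() * 0.5)

    def test_edaphic_layers_bit_identical_and_protected(self, env_small):
        out = apply_scenario(env_small, ScenarioShift("w", offsets={"BIO1": 1.0}))
        np.testing.assert_array_equal(out.layers["phh2o"], env_small.layers["phh2o"])
        with pytest.raises(ValueError, match="edaphic"):
            apply_scenario(env_small, ScenarioShift("bad", offsets={"phh2o": 1.0}))
        with pytest.raises(ValueError, match="factors"):
            ScenarioShift("bad", factors={"BIO1": -1.0})


class TestGenerateLandcover:
    def test_single_class_uniform(self, grid_small):
        lc = generate_landcover(grid_small, {"forest": 1.0}, seed=0)
        assert (lc.codes == 0).all()
        assert lc.classes == {0: "forest"}

    def test_two_class_realized_fractions(self):
        grid = GridSpec.from_bounds(0, 0, 100 * 2.5 / 60, 100 * 2.5 / 60)
        lc = generate_landcover(grid, {"a": 0.5, "b": 0.5}, seed=1)
        frac_a = (lc.codes == 0).mean()
        assert 0.45 <= frac_a <= 0.55

    def test_determinism_and_validation(self, grid_small):
        l1 = generate_landcover(grid_small, {"a": 0.3, "b": 0.7}, seed=2)
        l2 = generate_landcover(grid_small, {"a": 0.3, "b": 0.7}, seed=2)
        np.testing.assert_array_equal(l1.codes, l2.codes)
        with pytest.raises(ValueError, match="nonempty"):
            generate_landcover(grid_small, {})
        with pytest.raises(ValueError, match="sum"):
            generate_landcover(grid_small, {"a": 0.2, "b": 0.2})
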
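"""Shared study system for the example scripts: a 5x5-degree synthetic
region with three environmental layers and one virtual focal species."""

from shaderange import (
    GridSpec,
    LayerSpec,
    NicheResponse,
    SpeciesNicheTruth,
    generate_env_stack,
    generate_land_mask,
)


def build_study_system():
    grid = GridSpec.from_bounds(-10.0, 2.0, -5.0, 7.0)  # 120x120 at 2.5 arc-min
    mask = generate_land_mask(grid, ocean_fraction=0.2, seed=1)
    env = generate_env_stack(grid, [
        LayerSpec("BIO1", "climatic", mean=26.0, sd=1.5, smoothing=5.0,
                  gradient=-0.4),
        LayerSpec("BIO12", "climatic", mean=1800.0, sd=400.0, smoothing=5.0),
        LayerSpec("phh2o", "edaphic", mean=58.0, sd=6.0, smoothing=3.0),
    ], seed=1, nodata_mask=mask)
    species = SpeciesNicheTruth("virtual_cocoa", {
        "BIO1": NicheResponse(optimum=26.5, tolerance=1.2),
        "BIO12": NicheResponse(optimum=2000.0, tolerance=350.0),
    }, prevalence_target=0.25)
    return grid, env, species
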
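"""Self-contained demo study system written to disk.

Builds a small West-Africa-like study region with six environmental layers
(four climatic, two edaphic), three virtual species (a focal "cocoa" plus
two shade trees) with contaminated occurrence samples, one future scenario
(SSP585 2041-2060) realized by two GCM variants, and a patchy land-cover
raster — then writes everything in the pipeline's on-disk formats together
with a ready-to-run YAML config.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .config import PipelineConfig, validate_config
from .grids import CLIMATIC, EDAPHIC, GridSpec
from .pipeline import derive_seed
from .synthetic import (
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
)

DEMO_LAYERS = [
    LayerSpec("BIO1", CLIMATIC, mean=26.0, sd=1.5, smoothing=6.0, gradient=-0.4),
    LayerSpec("BIO4", CLIMATIC, mean=150.0, sd=40.0, smoothing=8.0, gradient=8.0),
    LayerSpec("BIO12", CLIMATIC, mean=1800.0, sd=400.0, smoothing=6.0, gradient=-80.0),
    LayerSpec("BIO18", CLIMATIC, mean=450.0, sd=120.0, smoothing=5.0),
    LayerSpec("phh2o", EDAPHIC, mean=58.0, sd=6.0, smoothing=4.0),
    LayerSpec("cec", EDAPHIC, mean=160.0, sd=35.0, smoothing=4.0),
]


def demo_species(n_species: int = 3) -> list[SpeciesNicheTruth]:
    """Focal crop plus shade species with niches on known layer pairs."""
    catalog = [
        SpeciesNicheTruth("cocoa", {
            "BIO1": NicheResponse(26.5, 1.2),
            "BIO12": NicheResponse(2000.0, 350.0),
        }, prevalence_target=0.25),
        SpeciesNicheTruth("shade_albizia", {
            "BIO4": NicheResponse(130.0, 35.0),
            "BIO18": NicheResponse(500.0, 120.0),
        }, prevalence_target=0.3),
        SpeciesNicheTruth("shade_khaya", {
            "BIO1": NicheResponse(25.5, 1.5),
            "phh2o": NicheResponse(60.0, 7.0),
        }, prevalence_target=0.3),
    ]
    if not (1 <= n_species <= len(catalog)):
        raise ValueError(f"n_species must be in 1..{len(catalog)}")
    return catalog[:n_species]


def make_demo_inputs(directory: str | Path, seed: int = 0, n_species: int = 3,
                     n_clean: int = 150, grid: GridSpec | None = None,
                     n_pseudoabsences: int = 300, buffer_km: float = 300.0,
                     n_gcms: int = 2) -> Path:
    """Write demo inputs + config under ``directory``; returns the config path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grid = grid or GridSpec.from_bounds(-10.0, 2.0, -5.0, 7.0)
    mask = generate_land_mask(grid, ocean_fraction=0.2,
                              seed=derive_seed(seed, "demo", "mask"))
    env = generate_env_stack(grid, DEMO_LAYERS,
                             seed=derive_seed(seed, "demo", "env"),
                             nodata_mask=mask)
    io.write_stack(directory / "env_current", env)

    species = demo_species(n_species)
    tables = []
    for truth in species:
        tables.append(sample_occurrences(
            truth, env, n_clean=n_clean,
            contamination=Contamination(n_ocean=5, n_pre_baseline=5,
                                        n_duplicates=5, n_marginal=5),
            seed=derive_seed(seed, "demo", "occ", truth.species_id)))
    occ = pd.concat(tables, ignore_index=True)
    io.write_occurrences(directory / "occurrences.csv", occ)

    scenarios = []
    rng = np.random.default_rng(derive_seed(seed, "demo", "gcm"))
    for g in range(1, n_gcms + 1):
        # warming + drying with mild GCM-to-GCM spread
        shift = ScenarioShift(
            label=f"SSP585_2041-2060_GCM{g}",
            offsets={"BIO1": 2.0 + 0.3 * rng.standard_normal(),
                     "BIO4": 15.0 + 2.0 * rng.standard_normal()},
            factors={"BIO12": 0.9, "BIO18": 0.85},
        )
        fut = apply_scenario(env, shift)
        io.write_stack(directory / f"env_{shift.label}", fut)
        scenarios.append({"ssp": "SSP585", "period": "2041-2060",
                          "gcm": f"GCM{g}", "env_dir": f"env_{shift.label}"})

    lc = generate_landcover(grid, {
        "forest": 0.35, "shrubs": 0.2, "grassland": 0.15,
        "cropland": 0.15, "sparse_vegetation": 0.1, "urban": 0.05,
    }, seed=derive_seed(seed, "demo", "landcover"))
    io.write_landcover(directory / "landcover", lc)

    raw = {
        "paths": {"occurrences": "occurrences.csv", "env_dir": "env_current",
                  "landcover_dir": "landcover", "output_dir": "output"},
        "qc": {"min_n": 60},
        "pseudoabsence": {"n": n_pseudoabsences, "buffer_km": buffer_km},
        "model": {"hyperparams": {"GBM": {"n_estimators": 300},
                                  "RF": {"n_estimators": 200}}},
        "scenarios": scenarios,
        "community": {"min_richness": 1, "focal_species": "cocoa"},
        "seed": seed,
    }
    config_path = directory / "config.yml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
    validate_config(config_path)  # fail fast if the demo wrote a bad config
    return config_path
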
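"""Community-level products: stacked species richness, richness hotspots,
focal-crop overlap summaries and climatic/edaphic importance roll-ups.

Richness is the cellwise sum of per-species binary suitability maps
(stacked SDM). Hotspots are cells whose richness strictly exceeds a
threshold (default: more than 25 shade species). The overlap summary
characterizes, per shade species, the mean suitability of the focal crop
(cocoa) and the mean of a chosen environmental layer within the species'
own suitable range — and how both shift between current and future
scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import VariableImportance
from .grids import CLIMATIC, EDAPHIC, GridSpec
from .projection import BinaryMap, SuitabilityMap

DEFAULT_MIN_RICHNESS = 25


@dataclass
class RichnessMap:
    scenario: str
    counts: np.ndarray  # int, 0..n_species
    species: list[str]
    grid: GridSpec

    def __post_init__(self) -> None:
        if self.counts.shape != self.grid.shape:
            raise ValueError("raster shape does not match grid")


def richness(binaries: list[BinaryMap], scenario: str | None = None) -> RichnessMap:
    """Cellwise count of species with suitable habitat."""
    if not binaries:
        raise ValueError("need at least one binary map")
    grid = binaries[0].grid
    if any(b.grid != grid for b in binaries[1:]):
        raise ValueError("binary maps are not on a shared grid")
    counts = np.zeros(grid.shape, dtype=int)
    for b in binaries:
        counts += b.mask.astype(int)
    return RichnessMap(scenario=scenario or binaries[0].scenario, counts=counts,
                       species=[b.species_id for b in binaries], grid=grid)


def hotspots(rmap: RichnessMap, min_richness: int = DEFAULT_MIN_RICHNESS) -> np.ndarray:
    """Cells supporting strictly more than ``min_richness`` species."""
    if min_richness < 0:
        raise ValueError("min_richness must be >= 0")
    return rmap.counts > min_richness


def overlap_summary(binaries: dict[str, BinaryMap], focal: SuitabilityMap,
                    layer: np.ndarray, layer_name: str = "layer") -> pd.DataFrame:
    """Per-species means of focal-crop suitability and an environmental layer
    within that species' suitable area.

    Species with no suitable cells are flagged (``empty=True``) with NaN
    means rather than dropped.
    """
    if layer.shape != focal.grid.shape:
        raise ValueError("layer shape does not match focal map grid")
    rows = []
    for sp, b in binaries.items():
        if b.grid != focal.grid:
            raise ValueError(f"binary map for {sp!r} not on the focal grid")
        cells = b.mask
        n = int(cells.sum())
        if n == 0:
            rows.append({"species": sp, "n_cells": 0, "empty": True,
                         "mean_focal_suitability": np.nan,
                         f"mean_{layer_name}": np.nan})
            continue
        rows.append({
            "species": sp, "n_cells": n, "empty": False,
            "mean_focal_suitability": float(np.nanmean(focal.values[cells])),
            f"mean_{layer_name}": float(np.nanmean(layer[cells])),
        })
    return pd.DataFrame(rows)


def overlap_shift(current: pd.DataFrame, future: pd.DataFrame,
                  layer_name: str = "layer") -> pd.DataFrame:
    """Current -> future shift vector per species for the overlap summary."""
    merged = current.merge(future, on="species", suffixes=("_current", "_future"))
    merged["d_focal"] = (merged["mean_focal_suitability_future"]
                         - merged["mean_focal_suitability_current"])
    merged[f"d_{layer_name}"] = (merged[f"mean_{layer_name}_future"]
                                 - merged[f"mean_{layer_name}_current"])
    return merged


def importance_rollup(importances: list[VariableImportance],
                      variable_class: dict[str, str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species climatic/edaphic importance sums and pooled summaries.

    Returns (per_species, pooled): the per-species frame has one row per
    species with ``climatic`` and ``edaphic`` percentage sums (partitioning
    100); pooled has mean and median of each class across species.
    """
    rows = []
    for vi in importances:
        unknown = [n for n in vi.importance.index if n not in variable_class]
        if unknown:
            raise ValueError(f"variables missing from variable_class: {unknown}")
        sums = {cls: 0.0 for cls in (CLIMATIC, EDAPHIC)}
        for name, pct in vi.importance.items():
            sums[variable_class[name]] += float(pct)
        rows.append({"species": vi.species_id,
                     "best_algorithm": vi.best_algorithm, **sums})
    per_species = pd.DataFrame(rows)
    pooled = per_species[[CLIMATIC, EDAPHIC]].agg(["mean", "median"]).T
    pooled.index.name = "variable_class"
    return per_species, pooled.reset_index()
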
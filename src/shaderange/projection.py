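"""Map-space application of fitted ensembles: suitability rasters, GCM
consensus, binarization, land-cover masking and suitable-area accounting.

A species' ensemble, calibrated on current climate, is applied cellwise to
the current stack and to each future GCM stack; per SSP x period the GCM
suitability maps are averaged cellwise before binarization at the species'
training threshold (fit once on current conditions and reused — no future
re-thresholding). Suitable areas are summed from geodesic cell areas
(cos-latitude weighting) by default, optionally by raw cell counts. The
land-cover constraint restricts "usable" suitable area to classes where
agroforestry can expand without deforestation (shrubs, grassland, cropland,
sparse vegetation); land cover is held constant across scenarios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import EnsembleModel
from .grids import EnvStack, GridSpec, LandCoverMap

DEFAULT_ALLOWED_CLASSES = ("shrubs", "grassland", "cropland", "sparse_vegetation")

# change-raster codes
CHANGE_NONE, CHANGE_STABLE, CHANGE_GAIN, CHANGE_LOSS = 0, 1, 2, 3


@dataclass
class SuitabilityMap:
    species_id: str
    scenario: str
    values: np.ndarray  # float in [0,1] on land, NaN at nodata
    grid: GridSpec

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("raster shape does not match grid")


@dataclass
class BinaryMap:
    species_id: str
    scenario: str
    mask: np.ndarray  # bool; False at nodata
    threshold: float
    grid: GridSpec

    def __post_init__(self) -> None:
        if self.mask.shape != self.grid.shape:
            raise ValueError("raster shape does not match grid")


@dataclass
class AreaChangeSummary:
    """Suitable-area bookkeeping for one species under one scenario."""

    species_id: str
    scenario: str
    current_km2: float
    future_km2: float
    pct_of_study_area_current: float
    pct_change: float | None  # None when current area is zero
    masked_current_km2: float | None = None
    masked_future_km2: float | None = None
    masked_pct_of_study_area_current: float | None = None
    masked_pct_change: float | None = None


def predict_map(model: EnsembleModel, env: EnvStack,
                scenario: str = "current") -> SuitabilityMap:
    """Apply the ensemble cellwise over land; nodata propagates as NaN."""
    missing = [p for p in model.predictors if p not in env.layers]
    if missing:
        raise KeyError(f"stack missing model predictors: {missing}")
    rows, cols = np.where(env.land_mask)
    X = np.column_stack([env.layers[p][rows, cols] for p in model.predictors])
    values = np.full(env.grid.shape, np.nan)
    values[rows, cols] = model.predict(X)
    return SuitabilityMap(species_id=model.species_id, scenario=scenario,
                          values=values, grid=env.grid)


def aggregate_gcms(maps: list[SuitabilityMap], scenario: str | None = None) -> SuitabilityMap:
    """Cellwise mean suitability across GCM members of one SSP x period."""
    if not maps:
        raise ValueError("need at least one map")
    grid = maps[0].grid
    if any(m.grid != grid for m in maps[1:]):
        raise ValueError("maps are not on a shared grid")
    stack = np.stack([m.values for m in maps])
    return SuitabilityMap(species_id=maps[0].species_id,
                          scenario=scenario or maps[0].scenario,
                          values=stack.mean(axis=0), grid=grid)


def binarize(smap: SuitabilityMap, threshold: float) -> BinaryMap:
    """Suitable iff suitability >= threshold; NaN cells are unsuitable."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    with np.errstate(invalid="ignore"):
        mask = smap.values >= threshold
    return BinaryMap(species_id=smap.species_id, scenario=smap.scenario,
                     mask=mask, threshold=threshold, grid=smap.grid)


def mask_landcover(binary: BinaryMap, landcover: LandCoverMap,
                   allowed_classes) -> BinaryMap:
    """Restrict suitable cells to allowed land-cover classes.

    ``allowed_classes`` may name classes or give integer codes; unknown
    names raise, codes absent from the legend warn and count as not allowed.
    """
    if landcover.grid != binary.grid:
        raise ValueError("land cover and binary map are not on a shared grid")
    allowed_codes: set[int] = set()
    for cls in allowed_classes:
        if isinstance(cls, str):
            allowed_codes.add(landcover.code_for(cls))
        else:
            if int(cls) not in landcover.classes:
                warnings.warn(f"land-cover code {cls} not in legend; ignored",
                              stacklevel=2)
                continue
            allowed_codes.add(int(cls))
    ok = np.isin(landcover.codes, sorted(allowed_codes))
    return BinaryMap(species_id=binary.species_id, scenario=binary.scenario,
                     mask=binary.mask & ok, threshold=binary.threshold,
                     grid=binary.grid)


def suitable_area_km2(binary: BinaryMap, mode: str = "geodesic") -> float:
    """Total suitable area; geodesic cell areas by default, cell count
    otherwise."""
    if mode == "count":
        return float(binary.mask.sum())
    if mode != "geodesic":
        raise ValueError("mode must be 'geodesic' or 'count'")
    return float((binary.mask * binary.grid.cell_area_raster()).sum())


def change_raster(current: BinaryMap, future: BinaryMap) -> np.ndarray:
    """Gain/loss/stable categories; partitions both maps:
    gain + stable = future suitable, loss + stable = current suitable."""
    if current.grid != future.grid:
        raise ValueError("maps are not on a shared grid")
    out = np.full(current.grid.shape, CHANGE_NONE, dtype=np.int8)
    out[current.mask & future.mask] = CHANGE_STABLE
    out[~current.mask & future.mask] = CHANGE_GAIN
    out[current.mask & ~future.mask] = CHANGE_LOSS
    return out


def area_change(current: BinaryMap, future: BinaryMap,
                landcover: LandCoverMap | None = None,
                allowed_classes=DEFAULT_ALLOWED_CLASSES,
                study_area_mask: np.ndarray | None = None,
                mode: str = "geodesic") -> AreaChangeSummary:
    """Suitable-area change between scenarios, optionally under the
    land-cover constraint.

    ``study_area_mask`` (default: everywhere) defines the denominator of
    "percent of study area"; pass the land mask to exclude ocean.
    """
    if current.grid != future.grid:
        raise ValueError("maps are not on a shared grid")
    grid = current.grid
    if study_area_mask is None:
        study_area_mask = np.ones(grid.shape, dtype=bool)
    if mode == "count":
        study_area = float(study_area_mask.sum())
    else:
        study_area = float((study_area_mask * grid.cell_area_raster()).sum())

    def summarize(cur: BinaryMap, fut: BinaryMap):
        a_cur = suitable_area_km2(cur, mode=mode)
        a_fut = suitable_area_km2(fut, mode=mode)
        pct_study = 100.0 * a_cur / study_area
        pct_change = 100.0 * (a_fut - a_cur) / a_cur if a_cur > 0 else None
        return a_cur, a_fut, pct_study, pct_change

    a_cur, a_fut, pct_study, pct_change = summarize(current, future)
    out = AreaChangeSummary(
        species_id=current.species_id, scenario=future.scenario,
        current_km2=a_cur, future_km2=a_fut,
        pct_of_study_area_current=pct_study, pct_change=pct_change)
    if landcover is not None:
        m_cur = mask_landcover(current, landcover, allowed_classes)
        m_fut = mask_landcover(future, landcover, allowed_classes)
        out.masked_current_km2, out.masked_future_km2, \
            out.masked_pct_of_study_area_current, out.masked_pct_change = \
            summarize(m_cur, m_fut)
    return out


def summaries_to_frame(summaries: list[AreaChangeSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
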
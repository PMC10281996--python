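"""Virtual-species study system: synthetic rasters, niches and occurrences.

Every downstream stage of the pipeline (QC, pseudo-absence sampling,
predictor selection, ensemble modelling, projection, community stacking) is
exercised against data generated here, where the truth is known by
construction: spatially autocorrelated environmental fields standing in for
bioclim/soil rasters, virtual species with Gaussian niche responses,
occurrence samples contaminated with the error classes the cleaning cascade
must catch, multiplicative/additive climate shifts standing in for
GCM x SSP x period futures, and a patchy categorical land-cover raster.

Everything is a pure function of its parameters and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .grids import CLIMATIC, EDAPHIC, EnvStack, GridSpec, LandCoverMap


@dataclass(frozen=True)
class LayerSpec:
    """Recipe for one synthetic environmental layer.

    The layer is ``mean + sd * smoothed-noise + gradient * (lat - lat_mid)``;
    ``smoothing`` is the Gaussian kernel sigma in cells, giving the field its
    spatial autocorrelation length.
    """

    name: str
    var_class: str  # "climatic" | "edaphic"
    mean: float = 0.0
    sd: float = 1.0
    smoothing: float = 3.0
    gradient: float = 0.0


@dataclass(frozen=True)
class NicheResponse:
    """Gaussian suitability response to one layer: exp(-z^2/2), z=(x-opt)/tol."""

    optimum: float
    tolerance: float  # may be inf => flat response on this layer


@dataclass
class SpeciesNicheTruth:
    """Ground-truth niche of a virtual species.

    Suitability is the product of independent Gaussian responses over the
    named layers, rescaled so its mean over land approximates
    ``prevalence_target``.
    """

    species_id: str
    response_params: dict[str, NicheResponse]
    prevalence_target: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence_target < 1.0):
            raise ValueError("prevalence_target must be in (0, 1)")
        if not any(math.isfinite(r.tolerance) for r in self.response_params.values()):
            raise ValueError("at least one layer must have finite tolerance")


@dataclass(frozen=True)
class ScenarioShift:
    """Linear climate shift per layer: layer <- layer * factor + offset."""

    label: str
    offsets: dict[str, float] = field(default_factory=dict)
    factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError("scenario factors must be positive")

    @property
    def shifted_layers(self) -> set[str]:
        return set(self.offsets) | set(self.factors)


@dataclass(frozen=True)
class Contamination:
    """Counts of bad records to inject into an occurrence sample."""

    n_ocean: int = 0
    n_pre_baseline: int = 0
    n_duplicates: int = 0
    n_marginal: int = 0


def _smooth_unit_field(grid: GridSpec, smoothing: float, rng: np.random.Generator) -> np.ndarray:
    """Kernel-smoothed white noise restandardized to mean 0, sd 1."""
    field = rng.standard_normal(grid.shape)
    if smoothing > 0:
        field = ndimage.gaussian_filter(field, sigma=smoothing, mode="reflect")
    sd = field.std()
    if sd > 0:
        field = (field - field.mean()) / sd
    return field


def generate_land_mask(grid: GridSpec, ocean_fraction: float = 0.0,
                       seed: int = 0, smoothing: float = 8.0) -> np.ndarray:
    """Boolean nodata (ocean) mask covering ~ocean_fraction of the grid.

    Thresholding a smoothed field at its ocean_fraction quantile gives a
    contiguous coastline rather than salt-and-pepper water.
    """
    if not (0.0 <= ocean_fraction < 1.0):
        raise ValueError("ocean_fraction must be in [0, 1)")
    if ocean_fraction == 0.0:
        return np.zeros(grid.shape, dtype=bool)
    rng = np.random.default_rng(seed)
    field = _smooth_unit_field(grid, smoothing, rng)
    return field < np.quantile(field, ocean_fraction)


def generate_env_stack(grid: GridSpec, layer_specs: list[LayerSpec], seed: int = 0,
                       nodata_mask: np.ndarray | None = None) -> EnvStack:
    """Generate a stack of autocorrelated environmental layers.

    Deterministic given (grid, layer_specs, seed); each layer draws from an
    independent child stream of the seed so adding a layer does not perturb
    the others.
    """
    names = [s.name for s in layer_specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate layer names in layer_specs")
    if not layer_specs:
        raise ValueError("layer_specs must be nonempty")
    if nodata_mask is None:
        nodata_mask = np.zeros(grid.shape, dtype=bool)
    _, lat = grid.center_mesh()
    lat_mid = (grid.y_min + grid.y_max) / 2.0
    seeds = np.random.SeedSequence(seed).spawn(len(layer_specs))
    layers: dict[str, np.ndarray] = {}
    classes: dict[str, str] = {}
    for spec, child in zip(layer_specs, seeds):
        if spec.smoothing < 0:
            raise ValueError(f"layer {spec.name!r}: smoothing must be >= 0")
        rng = np.random.default_rng(child)
        noise = _smooth_unit_field(grid, spec.smoothing, rng) if spec.sd > 0 else 0.0
        layers[spec.name] = spec.mean + spec.sd * noise + spec.gradient * (lat - lat_mid)
        classes[spec.name] = spec.var_class
    return EnvStack(grid=grid, layers=layers, nodata_mask=nodata_mask,
                    variable_class=classes)


def true_suitability(truth: SpeciesNicheTruth, env: EnvStack,
                     rescale: bool = True) -> np.ndarray:
    """Ground-truth suitability raster in [0, 1]; NaN on nodata cells.

    The raw surface is the product of per-layer Gaussian responses
    ``exp(-0.5 * ((x - opt) / tol)^2)``. With ``rescale=True`` it is scaled
    (with clipping at 1) so its mean over land equals the species'
    prevalence target.
    """
    missing = [n for n in truth.response_params if n not in env.layers]
    if missing:
        raise KeyError(f"niche references layers absent from stack: {missing}")
    suit = np.ones(env.grid.shape)
    for name, resp in truth.response_params.items():
        if not math.isfinite(resp.tolerance):
            continue
        z = (env.layers[name] - resp.optimum) / resp.tolerance
        suit *= np.exp(-0.5 * z**2)
    land = env.land_mask
    if not rescale:
        out = np.where(land, suit, np.nan)
        return out
    mean_raw = suit[land].mean()
    if mean_raw <= 0:
        raise ValueError("niche response is zero everywhere on land")
    target = truth.prevalence_target
    if target <= mean_raw:
        scaled = suit * (target / mean_raw)
    else:
        # need amplification with clipping at 1; solve for the factor
        positive_frac = (suit[land] > 0).mean()
        if target >= positive_frac:
            raise ValueError("prevalence target unattainable: too few suitable cells")
        f = lambda c: np.clip(c * suit[land], 0.0, 1.0).mean() - target
        c = optimize.brentq(f, 1.0, 1e12)
        scaled = np.clip(c * suit, 0.0, 1.0)
    return np.where(land, scaled, np.nan)


def _sample_cells(rng: np.random.Generator, rows: np.ndarray, cols: np.ndarray,
                  weights: np.ndarray | None, n: int) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.choice(len(rows), size=n, replace=True, p=weights)
    return rows[idx], cols[idx]


def sample_occurrences(truth: SpeciesNicheTruth, env: EnvStack, n_clean: int,
                       contamination: Contamination | None = None, seed: int = 0,
                       year_range: tuple[int, int] = (1970, 2020),
                       jitter: float = 0.4) -> pd.DataFrame:
    """Draw a contaminated occurrence table for a virtual species.

    Clean records are drawn from land cells with probability proportional to
    true suitability, with sub-cell coordinate jitter (|dx| <= jitter * cell)
    and collection years within ``year_range``. Injected error classes are
    recorded in a hidden ``truth`` column so QC filters can be scored
    exactly:

    - ``ocean``: placed on nodata cells;
    - ``pre_baseline``: on land but dated before 1969;
    - ``duplicate``: exact copies of clean rows;
    - ``marginal``: placed at the climatically most extreme land cells.
    """
    if n_clean < 1:
        raise ValueError("n_clean must be >= 1")
    contamination = contamination or Contamination()
    rng = np.random.default_rng(seed)
    grid = env.grid
    suit = true_suitability(truth, env)
    land_rows, land_cols = np.where(env.land_mask)
    weights = suit[land_rows, land_cols]
    weights = weights / weights.sum()

    def jittered(rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lon, lat = grid.cell_center(rows, cols)
        lon = lon + rng.uniform(-jitter, jitter, size=len(rows)) * grid.resolution
        lat = lat + rng.uniform(-jitter, jitter, size=len(rows)) * grid.resolution
        return lon, lat

    frames = []
    r, c = _sample_cells(rng, land_rows, land_cols, weights, n_clean)
    lon, lat = jittered(r, c)
    frames.append(pd.DataFrame({
        "species": truth.species_id, "lon": lon, "lat": lat,
        "year": rng.integers(year_range[0], year_range[1] + 1, size=n_clean),
        "source": "survey", "truth": "clean",
    }))

    if contamination.n_ocean > 0:
        oc_rows, oc_cols = np.where(env.nodata_mask)
        if len(oc_rows) < 1 or contamination.n_ocean > len(oc_rows):
            raise ValueError(
                f"cannot place {contamination.n_ocean} ocean records: "
                f"only {len(oc_rows)} nodata cells")
        idx = rng.choice(len(oc_rows), size=contamination.n_ocean, replace=False)
        lon, lat = jittered(oc_rows[idx], oc_cols[idx])
        frames.append(pd.DataFrame({
            "species": truth.species_id, "lon": lon, "lat": lat,
            "year": rng.integers(year_range[0], year_range[1] + 1,
                                 size=contamination.n_ocean),
            "source": "survey", "truth": "ocean",
        }))

    if contamination.n_pre_baseline > 0:
        r, c = _sample_cells(rng, land_rows, land_cols, weights,
                             contamination.n_pre_baseline)
        lon, lat = jittered(r, c)
        frames.append(pd.DataFrame({
            "species": truth.species_id, "lon": lon, "lat": lat,
            "year": rng.integers(1900, 1969, size=contamination.n_pre_baseline),
            "source": "survey", "truth": "pre_baseline",
        }))

    if contamination.n_duplicates > 0:
        base = frames[0]
        idx = rng.integers(0, n_clean, size=contamination.n_duplicates)
        dup = base.iloc[idx].copy()
        dup["truth"] = "duplicate"
        frames.append(dup.reset_index(drop=True))

    if contamination.n_marginal > 0:
        climatic = [n for n in env.layers if env.variable_class[n] == CLIMATIC]
        if not climatic:
            raise ValueError("marginal contamination requires a climatic layer")
        layer = env.layers[climatic[0]]
        vals = layer[land_rows, land_cols]
        if contamination.n_marginal > len(vals):
            raise ValueError("more marginal records than land cells")
        order = np.argsort(vals)[::-1][: contamination.n_marginal]  # most extreme high end
        lon, lat = jittered(land_rows[order], land_cols[order])
        frames.append(pd.DataFrame({
            "species": truth.species_id, "lon": lon, "lat": lat,
            "year": rng.integers(year_range[0], year_range[1] + 1,
                                 size=contamination.n_marginal),
            "source": "survey", "truth": "marginal",
        }))

    return pd.concat(frames, ignore_index=True)


def apply_scenario(env: EnvStack, shift: ScenarioShift) -> EnvStack:
    """Apply a linear climate shift; edaphic layers pass through unchanged."""
    for name in shift.shifted_layers:
        if name not in env.layers:
            raise KeyError(f"scenario shifts unknown layer {name!r}")
        if env.variable_class[name] == EDAPHIC:
            raise ValueError(
                f"scenario shifts edaphic layer {name!r}; soils are held constant")
    new_layers: dict[str, np.ndarray] = {}
    for name, arr in env.layers.items():
        if name in shift.shifted_layers:
            new_layers[name] = arr * shift.factors.get(name, 1.0) + shift.offsets.get(name, 0.0)
        else:
            new_layers[name] = arr.copy()
    return EnvStack(grid=env.grid, layers=new_layers,
                    nodata_mask=env.nodata_mask.copy(),
                    variable_class=dict(env.variable_class))


def generate_landcover(grid: GridSpec, class_fractions: dict[str, float],
                       seed: int = 0, smoothing: float = 6.0) -> LandCoverMap:
    """Patchy categorical land-cover raster with approximately the requested
    class fractions.

    Classes are carved out of a single smoothed random field by its
    cumulative-fraction quantiles, so patches are spatially contiguous and
    realized fractions match the request up to ties in the field.
    """
    if not class_fractions:
        raise ValueError("class_fractions must be nonempty")
    fracs = np.array(list(class_fractions.values()), dtype=float)
    if (fracs < 0).any():
        raise ValueError("class fractions must be nonnegative")
    total = fracs.sum()
    if not math.isclose(total, 1.0, abs_tol=0.01):
        raise ValueError(f"class fractions must sum to ~1 (got {total})")
    fracs = fracs / total
    rng = np.random.default_rng(seed)
    field = _smooth_unit_field(grid, smoothing, rng)
    edges = np.quantile(field, np.cumsum(fracs)[:-1])
    codes = np.searchsorted(edges, field, side="right").astype(np.uint8)
    classes = {i: name for i, name in enumerate(class_fractions)}
    return LandCoverMap(grid=grid, codes=codes, classes=classes)
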
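"""Background (pseudo-absence) sampling within a distance buffer of presences.

The presence-only algorithms are calibrated against 1000 pseudo-absences per
species, drawn uniformly from land cells lying within 500 km great-circle
distance of at least one presence but not themselves containing a presence.
The sampling unit is the grid cell (without replacement), with points placed
at cell centers; distances are haversine between cell centers with Earth
radius 6371 km, and the buffer is the union of per-presence discs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import BallTree

from .grids import EARTH_RADIUS_KM, EnvStack

DEFAULT_N = 1000
DEFAULT_BUFFER_KM = 500.0


@dataclass
class PseudoAbsenceSet:
    """Sampled background points for one species."""

    species_id: str
    points: np.ndarray  # (n, 2) lon, lat at cell centers
    seed: int
    buffer_km: float = DEFAULT_BUFFER_KM
    n: int = DEFAULT_N

    @property
    def lon(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def lat(self) -> np.ndarray:
        return self.points[:, 1]


def _nearest_presence_km(lons: np.ndarray, lats: np.ndarray,
                         p_lon: np.ndarray, p_lat: np.ndarray) -> np.ndarray:
    """Distance (km) from each query point to its nearest presence."""
    tree = BallTree(np.column_stack([np.radians(p_lat), np.radians(p_lon)]),
                    metric="haversine")
    d, _ = tree.query(np.column_stack([np.radians(lats), np.radians(lons)]), k=1)
    return d[:, 0] * EARTH_RADIUS_KM


def eligible_cells(presence_lon: np.ndarray, presence_lat: np.ndarray,
                   env: EnvStack, buffer_km: float = DEFAULT_BUFFER_KM) -> np.ndarray:
    """Boolean raster of cells eligible to receive a pseudo-absence.

    A cell is eligible iff it is land, its center lies strictly within
    ``buffer_km`` of at least one presence, and no presence falls in it.
    """
    p_lon = np.asarray(presence_lon, dtype=float)
    p_lat = np.asarray(presence_lat, dtype=float)
    if p_lon.size == 0:
        raise ValueError("need at least one presence")
    grid = env.grid
    land_rows, land_cols = np.where(env.land_mask)
    c_lon, c_lat = grid.cell_center(land_rows, land_cols)
    within = _nearest_presence_km(c_lon, c_lat, p_lon, p_lat) < buffer_km
    eligible = np.zeros(grid.shape, dtype=bool)
    eligible[land_rows[within], land_cols[within]] = True
    pr, pc = grid.cell_of(p_lon, p_lat)
    on_grid = pr >= 0
    eligible[pr[on_grid], pc[on_grid]] = False
    if not eligible.any():
        raise ValueError("no eligible pseudo-absence cells within the buffer")
    return eligible


def sample_pseudoabsences(presence_lon, presence_lat, env: EnvStack,
                          n: int = DEFAULT_N,
                          buffer_km: float = DEFAULT_BUFFER_KM,
                          seed: int = 0,
                          species_id: str = "species") -> PseudoAbsenceSet:
    """Draw ``n`` pseudo-absence points uniformly over eligible cells.

    Cells are sampled without replacement; raises if fewer than ``n`` cells
    are eligible, reporting the shortfall.
    """
    mask = eligible_cells(presence_lon, presence_lat, env, buffer_km=buffer_km)
    rows, cols = np.where(mask)
    if len(rows) < n:
        raise ValueError(
            f"only {len(rows)} eligible cells for {n} pseudo-absences "
            f"(short by {n - len(rows)})")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, replace=False)
    lon, lat = env.grid.cell_center(rows[idx], cols[idx])
    return PseudoAbsenceSet(species_id=species_id,
                            points=np.column_stack([lon, lat]),
                            seed=seed, buffer_km=buffer_km, n=n)
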
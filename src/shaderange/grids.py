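"""Raster grid geometry and the multi-layer environmental stack.

Everything in the pipeline lives on a single north-up lon/lat (WGS84) grid of
square cells, conventionally at 2.5 arc-minute resolution (~4.6 km at the
equator). Row 0 is the northernmost row; coordinates refer to cell centers;
extents are half-open ``[min, max)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: default cell size: 2.5 arc-minutes in degrees
DEFAULT_RESOLUTION = 2.5 / 60.0

CLIMATIC = "climatic"
EDAPHIC = "edaphic"


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up lon/lat raster grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; row 0 is the northernmost row.
    x_min, y_min, x_max, y_max
        Outer edges of the grid in degrees lon/lat.
    resolution
        Cell size in degrees (cells are square in degree space).
    """

    n_rows: int
    n_cols: int
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    resolution: float = DEFAULT_RESOLUTION

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for n, lo, hi, what in (
            (self.n_cols, self.x_min, self.x_max, "x"),
            (self.n_rows, self.y_min, self.y_max, "y"),
        ):
            if not math.isclose((hi - lo) / self.resolution, n, rel_tol=0, abs_tol=1e-6):
                raise ValueError(
                    f"{what} extent {hi - lo} is not {n} cells of {self.resolution} degrees"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def x_centers(self) -> np.ndarray:
        """Longitudes of cell centers, west to east."""
        return self.x_min + (np.arange(self.n_cols) + 0.5) * self.resolution

    def y_centers(self) -> np.ndarray:
        """Latitudes of cell centers, north to south (row order)."""
        return self.y_max - (np.arange(self.n_rows) + 0.5) * self.resolution

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) 2-D arrays of every cell center."""
        lon, lat = np.meshgrid(self.x_centers(), self.y_centers())
        return lon, lat

    def cell_of(self, lon, lat):
        """Map coordinates to (row, col) index arrays; -1 marks out-of-extent."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.x_min) / self.resolution)
        row = np.floor((self.y_max - lat) / self.resolution)
        with np.errstate(invalid="ignore"):
            inside = (
                (lon >= self.x_min)
                & (lon < self.x_max)
                & (lat > self.y_min)
                & (lat <= self.y_max)
            )
        row = np.where(inside, row, -1).astype(int)
        col = np.where(inside, col, -1).astype(int)
        return row, col

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.x_min + (col + 0.5) * self.resolution
        lat = self.y_max - (row + 0.5) * self.resolution
        return lon, lat

    def row_areas_km2(self) -> np.ndarray:
        """Geodesic area of one cell in each row, km^2.

        Spherical formula R^2 * dlam * (sin(phi_top) - sin(phi_bot)); area
        shrinks with |latitude|, so identical cell counts at different rows
        give different areas.
        """
        rows = np.arange(self.n_rows)
        lat_top = np.radians(self.y_max - rows * self.resolution)
        lat_bot = np.radians(self.y_max - (rows + 1) * self.resolution)
        dlam = math.radians(self.resolution)
        return EARTH_RADIUS_KM**2 * dlam * (np.sin(lat_top) - np.sin(lat_bot))

    def cell_area_raster(self) -> np.ndarray:
        return np.repeat(self.row_areas_km2()[:, None], self.n_cols, axis=1)


def _grid_from_bounds(
    x_min: float,
    y_min: float,
    x_max: float,
    y_max: float,
    resolution: float = DEFAULT_RESOLUTION,
) -> GridSpec:
    n_cols = round((x_max - x_min) / resolution)
    n_rows = round((y_max - y_min) / resolution)
    return GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        x_min=x_min,
        y_min=y_min,
        x_max=x_min + n_cols * resolution,
        y_max=y_min + n_rows * resolution,
        resolution=resolution,
    )


GridSpec.from_bounds = staticmethod(_grid_from_bounds)  # type: ignore[assignment]


@dataclass
class EnvStack:
    """Named environmental raster layers sharing one grid and nodata mask.

    ``nodata_mask`` is True where there is no data (ocean / outside the study
    area); it is shared by every layer. ``variable_class`` tags each layer as
    climatic (bioclim) or edaphic (soil), which drives the scenario-shift
    contract (edaphic layers are held constant under future climates) and the
    importance roll-ups.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray]
    nodata_mask: np.ndarray
    variable_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("EnvStack needs at least one layer")
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.grid.shape:
            raise ValueError("nodata mask shape does not match grid")
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}")
        missing = set(self.layers) - set(self.variable_class)
        if missing:
            raise ValueError(f"variable_class missing for layers: {sorted(missing)}")
        bad = {v for v in self.variable_class.values()} - {CLIMATIC, EDAPHIC}
        if bad:
            raise ValueError(f"unknown variable classes: {sorted(bad)}")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def land_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def layers_of_class(self, cls: str) -> list[str]:
        return [n for n in self.layers if self.variable_class[n] == cls]

    def extract(self, lon, lat, layer_names: list[str] | None = None) -> pd.DataFrame:
        """Point-extract layer values at coordinates.

        Points outside the grid or on nodata cells get NaN for every layer.
        """
        names = layer_names if layer_names is not None else self.layer_names
        row, col = self.grid.cell_of(lon, lat)
        inside = row >= 0
        valid = inside.copy()
        valid[inside] &= ~self.nodata_mask[row[inside], col[inside]]
        out = {}
        for name in names:
            if name not in self.layers:
                raise KeyError(f"layer {name!r} not in stack")
            vals = np.full(row.shape, np.nan)
            vals[valid] = self.layers[name][row[valid], col[valid]]
            out[name] = vals
        return pd.DataFrame(out)

    def copy(self) -> "EnvStack":
        return EnvStack(
            grid=self.grid,
            layers={k: v.copy() for k, v in self.layers.items()},
            nodata_mask=self.nodata_mask.copy(),
            variable_class=dict(self.variable_class),
        )


@dataclass
class LandCoverMap:
    """Categorical land-cover raster with integer class codes."""

    grid: GridSpec
    codes: np.ndarray
    classes: dict[int, str]

    def __post_init__(self) -> None:
        if self.codes.shape != self.grid.shape:
            raise ValueError("land-cover raster shape does not match grid")

    def code_for(self, name: str) -> int:
        for code, cls in self.classes.items():
            if cls == name:
                return code
        raise KeyError(f"unknown land-cover class {name!r}")


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance between coordinate arrays, km (broadcasting)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
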
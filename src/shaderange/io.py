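"""File I/O: ESRI ASCII grids, environmental-stack directories, occurrence CSVs.

Rasters are stored as plain-text ESRI ASCII grids (``.asc``), one file per
layer, with a ``stack.yml`` sidecar recording layer order, variable classes
and (for land cover) the class-code legend. Occurrence tables are CSV with
columns ``species,lon,lat,year,source``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grids import EnvStack, GridSpec, LandCoverMap

NODATA = -9999.0

OCCURRENCE_COLUMNS = ["species", "lon", "lat", "year", "source"]


def write_ascii_grid(path: str | os.PathLike, array: np.ndarray, grid: GridSpec,
                     nodata: float = NODATA, fmt: str = "%.6g") -> None:
    """Write a 2-D raster as an ESRI ASCII grid; NaN cells become nodata."""
    arr = np.asarray(array, dtype=float)
    if arr.shape != grid.shape:
        raise ValueError("array shape does not match grid")
    out = np.where(np.isnan(arr), nodata, arr)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x_min!r}\n"
        f"yllcorner {grid.y_min!r}\n"
        f"cellsize {grid.resolution!r}\n"
        f"NODATA_value {nodata!r}"
    )
    np.savetxt(path, out, fmt=fmt, header=header, comments="")


def read_ascii_grid(path: str | os.PathLike) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    res = header["cellsize"]
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        x_min=header["xllcorner"],
        y_min=header["yllcorner"],
        x_max=header["xllcorner"] + n_cols * res,
        y_max=header["yllcorner"] + n_rows * res,
        resolution=res,
    )
    data = data.reshape(n_rows, n_cols)
    data = np.where(data == header["nodata_value"], np.nan, data)
    return data, grid


def write_stack(directory: str | os.PathLike, stack: EnvStack) -> None:
    """Write every layer of a stack as .asc plus a stack.yml sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in stack.layers.items():
        masked = np.where(stack.nodata_mask, np.nan, arr)
        write_ascii_grid(directory / f"{name}.asc", masked, stack.grid)
    sidecar = {
        "layers": [
            {"name": n, "class": stack.variable_class[n]} for n in stack.layer_names
        ]
    }
    with open(directory / "stack.yml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)


def read_stack(directory: str | os.PathLike) -> EnvStack:
    """Read a stack directory written by :func:`write_stack`."""
    directory = Path(directory)
    with open(directory / "stack.yml") as fh:
        sidecar = yaml.safe_load(fh)
    layers: dict[str, np.ndarray] = {}
    classes: dict[str, str] = {}
    grid = None
    mask = None
    for entry in sidecar["layers"]:
        name = entry["name"]
        arr, g = read_ascii_grid(directory / f"{name}.asc")
        if grid is None:
            grid = g
            mask = np.isnan(arr)
        elif g != grid:
            raise ValueError(f"layer {name!r} grid differs from the first layer")
        layers[name] = np.where(np.isnan(arr), 0.0, arr)
        classes[name] = entry["class"]
    assert grid is not None and mask is not None
    return EnvStack(grid=grid, layers=layers, nodata_mask=mask, variable_class=classes)


def write_landcover(directory: str | os.PathLike, lc: LandCoverMap) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(directory / "landcover.asc", lc.codes.astype(float), lc.grid, fmt="%d")
    with open(directory / "landcover.yml", "w") as fh:
        yaml.safe_dump({"classes": {int(k): v for k, v in lc.classes.items()}}, fh)


def read_landcover(directory: str | os.PathLike) -> LandCoverMap:
    directory = Path(directory)
    arr, grid = read_ascii_grid(directory / "landcover.asc")
    with open(directory / "landcover.yml") as fh:
        sidecar = yaml.safe_load(fh)
    codes = np.where(np.isnan(arr), -1, arr).astype(int)
    return LandCoverMap(grid=grid, codes=codes,
                        classes={int(k): v for k, v in sidecar["classes"].items()})


def read_occurrences(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(OCCURRENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"occurrence file missing columns: {sorted(missing)}")
    return df


def write_occurrences(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)
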
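"""Lightweight raster grid containers on a local projected km coordinate system.

All layers live on a shared regular grid: cell ``(i, j)`` (column ``i``, row
``j``) has its lower-left corner at ``(x0 + i*cell, y0 + j*cell)`` km and its
centroid at ``(x0 + (i+0.5)*cell, y0 + (j+0.5)*cell)`` km, with cell ``(0, 0)``
at the lower-left of the domain.  Arrays are indexed ``[j, i]`` (row = y).

Layers are written as single-band TIFF (float32, NODATA -9999; binary uint8,
NODATA 255) with a JSON sidecar carrying the grid transform, because the
coordinate system is a local projection rather than a geographic CRS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

FLOAT_NODATA = -9999.0
BYTE_NODATA = 255


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid in projected km."""

    nx: int
    ny: int
    cell_size: float = 1.0
    x0: float = 0.0
    y0: float = 0.0

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in km."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.nx * self.cell_size,
            self.y0 + self.ny * self.cell_size,
        )

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape (ny, nx)."""
        return (self.ny, self.nx)

    def cell_index(self, x, y):
        """Column/row indices of the cells containing points ``(x, y)``.

        Returns integer arrays ``(i, j)``; points outside the extent get -1.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        i = np.floor((x - self.x0) / self.cell_size).astype(int)
        j = np.floor((y - self.y0) / self.cell_size).astype(int)
        bad = (i < 0) | (i >= self.nx) | (j < 0) | (j >= self.ny)
        i = np.where(bad, -1, i)
        j = np.where(bad, -1, j)
        return i, j

    def centroids(self):
        """Centroid coordinate arrays ``(X, Y)``, each of shape (ny, nx)."""
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(self.ny) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def to_dict(self) -> dict:
        return {
            "nx": self.nx,
            "ny": self.ny,
            "cell_size": self.cell_size,
            "x0": self.x0,
            "y0": self.y0,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


@dataclass
class Raster:
    """A single-band raster on a :class:`GridSpec`.

    ``values`` has shape (ny, nx); ``meta`` carries provenance such as
    species, season and mode.
    """

    values: np.ndarray
    grid: GridSpec
    nodata: float = FLOAT_NODATA
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"raster shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def copy(self) -> "Raster":
        return Raster(self.values.copy(), self.grid, self.nodata, dict(self.meta))


@dataclass
class EnvStack:
    """Co-registered environmental covariate layers.

    ``data`` has shape (n_layers, ny, nx); layers share the grid and the
    NODATA convention (cells NODATA in any layer are treated as NODATA
    everywhere).
    """

    names: list[str]
    data: np.ndarray
    grid: GridSpec
    nodata: float = FLOAT_NODATA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.names):
            raise ValueError("data must be (n_layers, ny, nx) matching names")
        if self.data.shape[1:] != self.grid.shape:
            raise ValueError("layer shape does not match grid")

    @property
    def n_layers(self) -> int:
        return len(self.names)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.all(self.data != self.nodata, axis=0)

    def values_at_cells(self, i, j) -> np.ndarray:
        """Layer values at cells (i, j) as an (n_points, n_layers) matrix."""
        return self.data[:, j, i].T.astype(float)

    def env_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """All valid cells as an (n_cells, n_layers) matrix plus (j, i) indices."""
        mask = self.valid_mask
        jj, ii = np.nonzero(mask)
        return self.values_at_cells(ii, jj), np.column_stack([jj, ii])


def write_raster(path: str | Path, raster: Raster) -> Path:
    """Write a single-band TIFF plus ``<name>.grid.json`` transform sidecar."""
    import tifffile

    path = Path(path)
    arr = raster.values
    if arr.dtype != np.uint8:
        arr = arr.astype(np.float32)
    tifffile.imwrite(path, arr)
    sidecar = path.with_suffix(path.suffix + ".grid.json")
    sidecar.write_text(
        json.dumps(
            {"grid": raster.grid.to_dict(), "nodata": float(raster.nodata),
             "meta": raster.meta},
            indent=1,
        )
    )
    return path


def read_raster(path: str | Path) -> Raster:
    import tifffile

    path = Path(path)
    arr = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".grid.json")
    info = json.loads(sidecar.read_text())
    return Raster(
        arr,
        GridSpec.from_dict(info["grid"]),
        nodata=info["nodata"],
        meta=info.get("meta", {}),
    )


def write_stack(out_dir: str | Path, stack: EnvStack) -> list[Path]:
    """Write one TIFF per layer; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, name in enumerate(stack.names):
        r = Raster(stack.data[k], stack.grid, nodata=stack.nodata,
                   meta={"layer": name})
        paths.append(write_raster(out_dir / f"{name}.tif", r))
    return paths


def read_stack(paths: list[str | Path]) -> EnvStack:
    rasters = [read_raster(p) for p in paths]
    grid = rasters[0].grid
    for r in rasters[1:]:
        if r.grid != grid:
            raise ValueError("layers are not co-registered")
    names = [r.meta.get("layer", Path(p).stem) for r, p in zip(rasters, paths)]
    data = np.stack([r.values for r in rasters])
    return EnvStack(names, data, grid, nodata=rasters[0].nodata)
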
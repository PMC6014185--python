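"""Lightweight georeferenced rasters on a north-up square grid.

All surfaces in the pipeline — covariates, suitability, prevalence,
population, burden — live on one aligned grid in a single projected
coordinate system whose units are kilometres.  A :class:`RasterGrid` is a
2-D float array plus an affine anchor (west edge, north edge, cell size)
and a boolean no-data mask; a :class:`RasterStack` is an ordered set of
rasters sharing that geometry bit-for-bit.

I/O uses the ESRI ASCII grid format (plain text, one file per band), which
round-trips exactly through ``repr`` floats and needs no binary reader.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "RasterStack", "read_ascii_grid"]

_NODATA = -9999.0


@dataclass
class RasterGrid:
    """A single-band raster on a regular, axis-aligned, north-up grid.

    Parameters
    ----------
    data
        2-D array of cell values, row 0 at the northern edge.
    west, north
        Coordinates (km) of the grid's west and north *edges*.
    cell
        Cell size in km (square cells).
    crs
        Identifier of the projected CRS; synthetic worlds use ``"local-km"``.
        Geographic (degree) CRS are refused by the terrain/distance operators.
    mask
        Boolean no-data mask, True where the cell carries no value.
    """

    data: np.ndarray
    west: float
    north: float
    cell: float
    crs: str = "local-km"
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.mask is None:
            self.mask = ~np.isfinite(self.data)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape must match data shape")

    # ------------------------------------------------------------------ geometry
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def south(self) -> float:
        return self.north - self.shape[0] * self.cell

    @property
    def east(self) -> float:
        return self.west + self.shape[1] * self.cell

    def same_grid(self, other: "RasterGrid") -> bool:
        """Bit-level equality of geometry (transform, CRS, shape)."""
        return (
            self.shape == other.shape
            and self.west == other.west
            and self.north == other.north
            and self.cell == other.cell
            and self.crs == other.crs
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-centre coordinates, each of grid shape."""
        rows, cols = self.shape
        x = self.west + (np.arange(cols) + 0.5) * self.cell
        y = self.north - (np.arange(rows) + 0.5) * self.cell
        return np.meshgrid(x, y)

    def xy_to_rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) under the half-open cell convention.

        Cells are [x0, x0+c) × (y0−c, y0]; a point on a shared edge belongs
        to the cell to the right / below.  No bounds clipping is applied.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.west) / self.cell).astype(int)
        row = np.floor((self.north - y) / self.cell).astype(int)
        # the north edge itself belongs to row 0
        row = np.where(np.asarray(self.north - y) == 0.0, 0, row)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.xy_to_rowcol(x, y)
        rows, cols = self.shape
        return (row >= 0) & (row < rows) & (col >= 0) & (col < cols)

    # ------------------------------------------------------------------ helpers
    def copy_with(self, data: np.ndarray, mask: np.ndarray | None = None) -> "RasterGrid":
        """New raster with the same geometry and different values."""
        return RasterGrid(
            data=np.asarray(data, dtype=float),
            west=self.west,
            north=self.north,
            cell=self.cell,
            crs=self.crs,
            mask=self.mask.copy() if mask is None else mask,
        )

    def valid_values(self) -> np.ndarray:
        return self.data[~self.mask]

    # ------------------------------------------------------------------ I/O
    def write_ascii(self, path: str | Path) -> None:
        """Write as an ESRI ASCII grid (text; nodata = -9999)."""
        rows, cols = self.shape
        out = self.data.copy()
        out[self.mask] = _NODATA
        buf = io.StringIO()
        buf.write(f"ncols {cols}\n")
        buf.write(f"nrows {rows}\n")
        buf.write(f"xllcorner {float(self.west)!r}\n")
        buf.write(f"yllcorner {float(self.south)!r}\n")
        buf.write(f"cellsize {float(self.cell)!r}\n")
        buf.write(f"NODATA_value {_NODATA!r}\n")
        for r in range(rows):
            buf.write(" ".join(repr(float(v)) for v in out[r]) + "\n")
        Path(path).write_text(buf.getvalue())


def read_ascii_grid(path: str | Path, crs: str = "local-km") -> RasterGrid:
    """Read an ESRI ASCII grid written by :meth:`RasterGrid.write_ascii`."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    cols = int(header["ncols"])
    rows = int(header["nrows"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", _NODATA)
    data = np.loadtxt(io.StringIO("\n".join(lines[body_start:]))).reshape(rows, cols)
    mask = data == nodata
    data = np.where(mask, np.nan, data)
    return RasterGrid(
        data=data,
        west=header["xllcorner"],
        north=header["yllcorner"] + rows * cell,
        cell=cell,
        crs=crs,
        mask=mask,
    )


class RasterStack:
    """An ordered collection of rasters sharing one grid exactly.

    No-data propagates: a cell masked in any layer is masked in the stack's
    combined mask, which is what feature extraction and prediction honour.
    """

    def __init__(self, layers: dict[str, RasterGrid]):
        if not layers:
            raise ValueError("a RasterStack needs at least one layer")
        self._layers = dict(layers)
        ref = next(iter(self._layers.values()))
        for name, grid in self._layers.items():
            if not grid.same_grid(ref):
                raise ValueError(
                    f"layer {name!r} is not aligned with the stack grid "
                    f"(transforms must match bit-for-bit)"
                )

    # mapping-ish surface
    def __getitem__(self, name: str) -> RasterGrid:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __len__(self) -> int:
        return len(self._layers)

    def __iter__(self):
        return iter(self._layers)

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    @property
    def grid(self) -> RasterGrid:
        """A reference layer carrying the shared geometry."""
        return next(iter(self._layers.values()))

    def combined_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid.shape, dtype=bool)
        for g in self._layers.values():
            mask |= g.mask
        return mask

    def as_array(self) -> np.ndarray:
        """(n_layers, rows, cols) array in insertion order."""
        return np.stack([self._layers[n].data for n in self._layers])

    def feature_matrix(self) -> np.ndarray:
        """(cells, n_layers) design matrix over all cells, NaN where masked."""
        arr = self.as_array().reshape(len(self), -1).T.copy()
        arr[self.combined_mask().ravel()] = np.nan
        return arr

    def write_dir(self, directory: str | Path) -> None:
        """One ASCII grid per layer, plus a names manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, grid in self._layers.items():
            grid.write_ascii(directory / f"{name}.asc")
        (directory / "layers.txt").write_text("\n".join(self._layers) + "\n")

    @classmethod
    def read_dir(cls, directory: str | Path, crs: str = "local-km") -> "RasterStack":
        directory = Path(directory)
        names = (directory / "layers.txt").read_text().split()
        return cls({n: read_ascii_grid(directory / f"{n}.asc", crs=crs) for n in names})
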
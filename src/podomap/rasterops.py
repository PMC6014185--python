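"""Covariate preprocessing: alignment, distances, slope, point extraction.

Operators mirror the raster toolchain of a disease-mapping study: nearest-
neighbour resampling onto one analysis grid, Euclidean distance-to-feature
surfaces in km, terrain slope in degrees from an elevation raster (Horn's
3×3 method), covariate standardisation, and extraction of covariate values
at community coordinates into the feature table both models consume.

Distance and slope are planar operators; rasters carrying a degree-unit
CRS are refused rather than silently treated as Cartesian.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .raster import RasterGrid, RasterStack

__all__ = [
    "resample_nearest",
    "euclidean_distance",
    "slope_degrees",
    "standardize_stack",
    "extract_features",
]

log = logging.getLogger(__name__)

_DEGREE_CRS_TOKENS = ("4326", "wgs84", "longlat", "degree")


def _refuse_degree_crs(grid: RasterGrid, op: str) -> None:
    if any(tok in grid.crs.lower() for tok in _DEGREE_CRS_TOKENS):
        raise ValueError(
            f"{op} needs a projected CRS in length units; got {grid.crs!r}. "
            "Project the raster first."
        )


def resample_nearest(src: RasterGrid, target: RasterGrid) -> RasterGrid:
    """Resample ``src`` onto the grid of ``target`` by nearest cell centre.

    Every output cell takes the value of the source cell whose centre is
    nearest to the output cell centre (ties on the half-cell boundary go to
    the cell right/below, the package-wide containment convention).
    No-data is preserved.  Disjoint extents are an error.
    """
    if src.crs != target.crs:
        raise ValueError(f"CRS mismatch: {src.crs!r} vs {target.crs!r}")
    if src.same_grid(target):
        return src.copy_with(src.data.copy(), src.mask.copy())
    if (
        src.east <= target.west
        or target.east <= src.west
        or src.north <= target.south
        or target.north <= src.south
    ):
        raise ValueError(
            "source and target extents are disjoint: "
            f"src=({src.west}, {src.south}, {src.east}, {src.north}) "
            f"target=({target.west}, {target.south}, {target.east}, {target.north})"
        )
    X, Y = target.cell_centers()
    srows, scols = src.shape
    # nearest source centre along each axis, clamped to the source extent
    col = np.clip(np.floor((X - src.west) / src.cell).astype(int), 0, scols - 1)
    row = np.clip(np.floor((src.north - Y) / src.cell).astype(int), 0, srows - 1)
    data = src.data[row, col]
    mask = src.mask[row, col]
    return RasterGrid(
        data=data, west=target.west, north=target.north, cell=target.cell,
        crs=target.crs, mask=mask,
    )


def euclidean_distance(points: np.ndarray, grid: RasterGrid) -> RasterGrid:
    """Per-cell straight-line distance (km) to the nearest feature point.

    ``points`` is an (n, 2) array of (x, y) coordinates.  Cells whose
    centre coincides with a feature get distance 0.
    """
    _refuse_degree_crs(grid, "euclidean_distance")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValueError("euclidean_distance needs at least one feature point")
    if points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of x,y coordinates")
    X, Y = grid.cell_centers()
    centers = np.column_stack([X.ravel(), Y.ravel()])
    dist, _ = cKDTree(points).query(centers, k=1)
    return grid.copy_with(dist.reshape(grid.shape))


def slope_degrees(elevation: RasterGrid, z_unit_per_km: float = 1000.0) -> RasterGrid:
    """Terrain slope in degrees from an elevation raster, Horn's 3×3 method.

    Horn's operator estimates the surface gradient from the eight
    neighbours with weights (1, 2, 1); edge cells use replicated borders,
    which reduces to one-sided differences there.  ``z_unit_per_km``
    converts elevation units to km (default: metres).
    """
    _refuse_degree_crs(elevation, "slope_degrees")
    rows, cols = elevation.shape
    if rows < 3 or cols < 3:
        raise ValueError("slope needs a grid of at least 3×3 cells")
    z = np.pad(elevation.data, 1, mode="edge") / z_unit_per_km  # km
    c = elevation.cell
    # neighbours: z[r-1+i, c-1+j] of the padded array
    nw, n_, ne = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    sw, s_, se = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dz_dx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * c)
    dz_dy = ((sw + 2 * s_ + se) - (nw + 2 * n_ + ne)) / (8 * c)
    slope = np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))
    return elevation.copy_with(slope)


def standardize_stack(stack: RasterStack) -> tuple[RasterStack, pd.DataFrame]:
    """Z-score every layer over its unmasked cells.

    Returns the standardized stack and a constants table (layer, mean, std)
    so extracted features and grid predictions stay on one scale.  Tree
    ensembles are scale-invariant; the geostatistical linear predictor is
    not, and benefits numerically.
    """
    layers = {}
    rows = []
    for name in stack.names:
        g = stack[name]
        vals = g.valid_values()
        mu, sd = float(vals.mean()), float(vals.std())
        if sd == 0:
            raise ValueError(f"layer {name!r} is constant; cannot standardize")
        layers[name] = g.copy_with((g.data - mu) / sd)
        rows.append({"layer": name, "mean": mu, "std": sd})
    return RasterStack(layers), pd.DataFrame(rows)


def extract_features(
    stack: RasterStack,
    surveys: pd.DataFrame,
    presence_threshold: int = 1,
) -> pd.DataFrame:
    """Extract covariate values at community coordinates.

    Each community row receives the values of the cell containing its
    point (half-open containment; edge points go right/below) plus an
    endemicity label: 1 if ``n_cases >= presence_threshold`` else 0.
    Points outside the grid or on no-data cells are dropped and the counts
    logged — the feature table used for fitting carries no missing values.

    Returns a DataFrame with columns ``community_id, x_km, y_km,
    n_screened, n_cases, <covariates...>, label, weight`` (weight
    initialised to 1).
    """
    grid = stack.grid
    x = surveys["x_km"].to_numpy(float)
    y = surveys["y_km"].to_numpy(float)
    inside = grid.contains(x, y)
    n_outside = int((~inside).sum())
    if n_outside:
        log.warning("dropping %d survey points outside the grid extent", n_outside)
    kept = surveys.loc[inside].reset_index(drop=True)
    row, col = grid.xy_to_rowcol(kept["x_km"].to_numpy(float), kept["y_km"].to_numpy(float))
    mask = stack.combined_mask()
    on_nodata = mask[row, col]
    n_nodata = int(on_nodata.sum())
    if n_nodata:
        log.warning("dropping %d survey points on no-data cells", n_nodata)
    kept = kept.loc[~on_nodata].reset_index(drop=True)
    row, col = row[~on_nodata], col[~on_nodata]
    out = kept.copy()
    for name in stack.names:
        out[name] = stack[name].data[row, col]
    out["label"] = (out["n_cases"] >= presence_threshold).astype(int)
    out["weight"] = 1.0
    out.attrs["covariates"] = stack.names
    out.attrs["n_dropped_outside"] = n_outside
    out.attrs["n_dropped_nodata"] = n_nodata
    return out
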
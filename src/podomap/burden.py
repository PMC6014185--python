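"""Population at risk and case-count estimation from prevalence surfaces.

The burden arithmetic is deliberately simple and exactly conservative:
per-cell cases = predicted prevalence × adult population, with the 95%
CI surfaces propagated by the same product; population at risk = adults
in cells inside the binary environmental-limits map; zonal aggregation
assigns each cell to the administrative polygon containing its centre
(with an "unassigned" residual row, so unit sums always reproduce the
grid totals).  A summariser derives the shares and threshold counts
burden tables are usually quoted by.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import shape as shapely_shape
from shapely.geometry import mapping
from shapely import intersects_xy
from shapely.geometry.base import BaseGeometry

from .geostat import PrevalencePrediction
from .raster import RasterGrid

__all__ = [
    "adult_population",
    "cases_surface",
    "population_at_risk",
    "aggregate",
    "summarize_endemicity",
    "region_shares",
    "load_region_burden_table",
    "read_admin_geojson",
    "write_admin_geojson",
]


def adult_population(
    pop: RasterGrid, adult_fraction: RasterGrid | float
) -> RasterGrid:
    """Adults per cell: total population × adult fraction (scalar or raster)."""
    if np.nanmin(pop.data[~pop.mask]) < 0:
        raise ValueError("population raster has negative cells")
    if isinstance(adult_fraction, RasterGrid):
        if not adult_fraction.same_grid(pop):
            raise ValueError("adult_fraction raster is not aligned with population")
        frac = adult_fraction.data
        valid = ~adult_fraction.mask
        if ((frac[valid] < 0) | (frac[valid] > 1)).any():
            raise ValueError("adult fraction outside [0, 1]")
        mask = pop.mask | adult_fraction.mask
    else:
        if not 0.0 <= float(adult_fraction) <= 1.0:
            raise ValueError("adult fraction outside [0, 1]")
        frac = float(adult_fraction)
        mask = pop.mask.copy()
    return pop.copy_with(pop.data * frac, mask=mask)


def cases_surface(
    prev: PrevalencePrediction, adults: RasterGrid
) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    """Cell-wise (mean, low, high) case counts: prevalence × adults.

    Grids must already be aligned — no silent resampling.  No-data
    propagates from either input.
    """
    if not adults.same_grid(prev.mean):
        raise ValueError(
            "adult-population raster is not aligned with the prevalence "
            "surfaces; resample explicitly first"
        )
    mask = prev.mean.mask | adults.mask
    out = []
    for surf in (prev.mean, prev.ci_low, prev.ci_high):
        data = surf.data * adults.data
        data[mask] = 0.0
        out.append(surf.copy_with(data, mask=mask.copy()))
    return tuple(out)


def population_at_risk(adults: RasterGrid, limits: RasterGrid) -> RasterGrid:
    """Adults living in cells classified environmentally suitable."""
    if not limits.same_grid(adults):
        raise ValueError("limits raster is not aligned with the adult population")
    data = np.where(limits.data > 0.5, adults.data, 0.0)
    mask = adults.mask | limits.mask
    data[mask] = 0.0
    return adults.copy_with(data, mask=mask)


# ------------------------------------------------------------------- zonal
def _check_overlaps(polygons: list[tuple[str, BaseGeometry]]) -> None:
    offenders = []
    for i in range(len(polygons)):
        for j in range(i + 1, len(polygons)):
            a, b = polygons[i][1], polygons[j][1]
            if a.intersection(b).area > 1e-9 * min(a.area, b.area):
                offenders.append((polygons[i][0], polygons[j][0]))
    if offenders:
        raise ValueError(f"administrative polygons overlap: {offenders}")


def aggregate(
    surfaces: dict[str, RasterGrid],
    polygons: list[tuple[str, BaseGeometry]],
) -> pd.DataFrame:
    """Zonal sums of the given surfaces over administrative polygons.

    Cells are assigned to the polygon containing their centre (boundary
    inclusive; a centre on a shared border lands in the first claiming
    polygon in list order — a deterministic tie rule).  Cells in
    no polygon accumulate in an ``unassigned`` row, so column totals equal
    grid totals exactly.
    """
    if not polygons:
        raise ValueError("need at least one polygon")
    _check_overlaps(polygons)
    ref = next(iter(surfaces.values()))
    for name, g in surfaces.items():
        if not g.same_grid(ref):
            raise ValueError(f"surface {name!r} is not aligned")
    X, Y = ref.cell_centers()
    x, y = X.ravel(), Y.ravel()
    assignment = np.full(x.size, -1, dtype=int)
    for k, (_, poly) in enumerate(polygons):
        free = assignment < 0
        if not free.any():
            break
        hit = intersects_xy(poly, x[free], y[free])
        idx = np.flatnonzero(free)[hit]
        assignment[idx] = k
    rows = []
    names = [n for n, _ in polygons] + ["unassigned"]
    for k, unit in enumerate(names):
        sel = assignment == (k if unit != "unassigned" else -1)
        row = {"unit": unit}
        for sname, g in surfaces.items():
            vals = g.data.ravel().copy()
            vals[g.mask.ravel()] = 0.0
            row[sname] = float(vals[sel].sum())
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.loc[out["unit"] == "unassigned"].iloc[0, 1:].sum() == 0:
        out = out[out["unit"] != "unassigned"].reset_index(drop=True)
    return out


# --------------------------------------------------------------- summaries
def summarize_endemicity(
    burden: pd.DataFrame,
    thresholds: tuple[float, ...] = (1, 100, 500),
    cases_col: str = "cases_mean",
) -> dict:
    """Counts of units whose estimated cases reach each threshold, plus
    each unit's share of the total and the largest-unit statistics."""
    if len(burden) == 0:
        return {
            "n_units": 0,
            "threshold_counts": {float(t): 0 for t in thresholds},
            "shares_pct": {},
            "largest_unit": None,
        }
    cases = burden[cases_col].to_numpy(float)
    total = cases.sum()
    shares = {
        str(u): (100.0 * c / total if total > 0 else 0.0)
        for u, c in zip(burden["unit"] if "unit" in burden else burden["region"], cases)
    }
    units = burden["unit"] if "unit" in burden else burden["region"]
    imax = int(np.argmax(cases))
    return {
        "n_units": int(len(burden)),
        "threshold_counts": {float(t): int((cases >= t).sum()) for t in thresholds},
        "shares_pct": shares,
        "largest_unit": {"unit": str(units.iloc[imax]), "cases": float(cases[imax]),
                         "share_pct": float(shares[str(units.iloc[imax])])},
        "total_cases": float(total),
    }


def region_shares(
    table: pd.DataFrame,
    regions: list[str],
    column: str = "cases_mean",
) -> float:
    """Percentage share of ``column`` held by the named regions (column
    sums as denominator, robust to presentation rounding of grand totals)."""
    key = "unit" if "unit" in table.columns else "region"
    total = table[column].sum()
    part = table.loc[table[key].isin(regions), column].sum()
    if len(table.loc[table[key].isin(regions)]) != len(regions):
        missing = set(regions) - set(table[key])
        raise ValueError(f"regions not in table: {sorted(missing)}")
    return float(100.0 * part / total)


def load_region_burden_table() -> pd.DataFrame:
    """Packaged regional burden estimates for Cameroon, 2015 (population at
    risk and adult podoconiosis cases with 95% bounds, one row per region)."""
    with resources.files("podomap.data").joinpath("cameroon_region_burden_2015.csv").open() as fh:
        return pd.read_csv(fh)


# ----------------------------------------------------------------- GeoJSON
def read_admin_geojson(path: str | Path) -> list[tuple[str, BaseGeometry]]:
    """Read (name, geometry) pairs from a GeoJSON FeatureCollection."""
    doc = json.loads(Path(path).read_text())
    out = []
    for feat in doc["features"]:
        name = feat.get("properties", {}).get("name", f"unit_{len(out)}")
        out.append((name, shapely_shape(feat["geometry"])))
    if not out:
        raise ValueError(f"no features in {path}")
    return out


def write_admin_geojson(
    polygons: list[tuple[str, BaseGeometry]], path: str | Path
) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"name": name},
                "geometry": mapping(geom),
            }
            for name, geom in polygons
        ],
    }
    Path(path).write_text(json.dumps(doc))
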
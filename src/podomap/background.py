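"""Sampling-bias surface, pseudo-absence generation and regression weights.

Presence records from disease surveys are geographically biased: one
region may be screened near-exhaustively while the rest of the country
gets a thin sample.  Presence-background learning corrects for this by
drawing background (pseudo-absence) points with the *same* spatial bias as
the occurrences.  The bias surface is a kernel-density smooth of per-cell
occurrence counts (Gaussian kernel, Silverman bandwidth by default);
background points are then drawn from it with replacement at cell centres.

Regression weights down-weight the absence + background records so their
summed weight equals that of the presences — the ensemble then learns to
discriminate environments rather than reproduce sampling effort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .raster import RasterGrid

__all__ = [
    "BiasSurface",
    "silverman_bandwidth",
    "build_bias_surface",
    "sample_background",
    "subsample_positives",
    "assign_weights",
]


@dataclass
class BiasSurface:
    """A per-cell sampling-intensity density (sums to 1 over unmasked cells)."""

    grid: RasterGrid
    bandwidth: float  # km

    @property
    def density(self) -> np.ndarray:
        return self.grid.data


def silverman_bandwidth(points: np.ndarray) -> float:
    """Silverman's rule on the pooled x/y coordinates (isotropic, d=2)."""
    points = np.atleast_2d(points)
    n = len(points)
    if n < 2:
        raise ValueError("Silverman bandwidth needs at least two points")
    sd = float(np.sqrt(points.var(axis=0, ddof=1).mean()))
    if sd == 0:
        raise ValueError("degenerate occurrence coordinates (zero spread)")
    return sd * n ** (-1.0 / 6.0)  # d=2 exponent


def build_bias_surface(
    occurrences: np.ndarray,
    grid: RasterGrid,
    bandwidth: float | None = None,
) -> BiasSurface:
    """Kernel-density sampling-bias surface from occurrence coordinates.

    Occurrence records are counted per cell (snapped to cell centres under
    the package containment convention), smoothed with an isotropic
    Gaussian kernel of the stated bandwidth, and renormalised to sum 1
    over unmasked cells.  ``bandwidth=None`` applies Silverman's rule.
    """
    occurrences = np.atleast_2d(np.asarray(occurrences, dtype=float))
    if occurrences.size == 0:
        raise ValueError("need at least one occurrence record")
    inside = grid.contains(occurrences[:, 0], occurrences[:, 1])
    if not inside.any():
        raise ValueError("all occurrence records fall outside the grid")
    occurrences = occurrences[inside]
    if bandwidth is None:
        bandwidth = silverman_bandwidth(occurrences)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")

    row, col = grid.xy_to_rowcol(occurrences[:, 0], occurrences[:, 1])
    counts = np.zeros(grid.shape)
    np.add.at(counts, (row, col), 1.0)

    X, Y = grid.cell_centers()
    centers = np.column_stack([X.ravel(), Y.ravel()])
    occupied = counts.ravel() > 0
    d2 = cdist(centers, centers[occupied], "sqeuclidean")
    dens = (np.exp(-0.5 * d2 / bandwidth**2) @ counts.ravel()[occupied]).reshape(grid.shape)
    dens[grid.mask] = 0.0
    total = dens.sum()
    if total <= 0:
        raise ValueError("bias surface degenerated to zero mass")
    dens /= total
    return BiasSurface(grid=grid.copy_with(dens), bandwidth=float(bandwidth))


def sample_background(
    bias: BiasSurface, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` background points at cell centres, weighted by the bias
    density, with replacement.  Returns an (n, 2) array of coordinates."""
    if n < 1:
        raise ValueError("n must be >= 1")
    dens = bias.density.ravel().copy()
    dens[bias.grid.mask.ravel()] = 0.0
    total = dens.sum()
    if total <= 0:
        raise ValueError("bias density is degenerate (all zero)")
    idx = rng.choice(dens.size, size=n, replace=True, p=dens / total)
    X, Y = bias.grid.cell_centers()
    return np.column_stack([X.ravel()[idx], Y.ravel()[idx]])


def subsample_positives(
    features: pd.DataFrame,
    in_region: np.ndarray,
    fraction: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Thin the positive communities of one over-represented region.

    Keeps ``floor(fraction × count)`` of the positive (label 1) rows whose
    ``in_region`` flag is set, sampled without replacement; every other row
    — positives elsewhere and all non-positives — is untouched.  Corrects
    the unbalanced representation of a near-exhaustively screened region.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    in_region = np.asarray(in_region, dtype=bool)
    if len(in_region) != len(features):
        raise ValueError("in_region flag must align with the feature table rows")
    pos_region = features.index[(features["label"] == 1) & in_region]
    k = int(np.floor(fraction * len(pos_region)))
    keep_pos = rng.choice(pos_region.to_numpy(), size=k, replace=False) if k else np.array([], dtype=int)
    drop = set(pos_region) - set(keep_pos.tolist())
    return features.loc[~features.index.isin(drop)].reset_index(drop=True)


def assign_weights(
    presences: pd.DataFrame,
    absences: pd.DataFrame,
    background: pd.DataFrame,
) -> pd.DataFrame:
    """Concatenate presences, observed absences and background points into
    one weighted training set.

    Presence rows get weight 1; absence and background rows share one
    common weight n_presence / (n_absence + n_background), so the summed
    weight of the non-presence records matches that of the presences.
    """
    n_pres = len(presences)
    if n_pres == 0:
        raise ValueError("need at least one presence record")
    n_other = len(absences) + len(background)
    if n_other == 0:
        raise ValueError("need at least one absence or background record")
    w = n_pres / n_other
    pres = presences.copy()
    pres["label"], pres["weight"] = 1, 1.0
    pres["record"] = "presence"
    absn = absences.copy()
    absn["label"], absn["weight"] = 0, w
    absn["record"] = "absence"
    back = background.copy()
    back["label"], back["weight"] = 0, w
    back["record"] = "background"
    out = pd.concat([pres, absn, back], ignore_index=True)
    out.attrs = dict(presences.attrs)
    assert abs(out.loc[out.record != "presence", "weight"].sum() - n_pres) < 1e-9
    return out
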
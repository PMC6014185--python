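"""Synthetic "mini-Cameroon" worlds for end-to-end pipeline testing.

Real podoconiosis mapping starts from survey microdata and satellite
covariates that are not redistributable.  This module generates a fully
synthetic stand-in with a *known* truth so that every downstream stage —
bias-corrected background sampling, the BRT/RF suitability ensemble, the
binomial geostatistical model and the burden arithmetic — can be validated
by parameter and surface recovery:

* spatially autocorrelated covariate rasters (exact Gaussian-process
  simulation, exponential correlation);
* a true prevalence surface p(x) = logit⁻¹(d(x)ᵀβ + S(x)) with S a
  zero-mean GP of partial sill σ² and range φ, and a derived binary
  suitability truth p(x) > floor;
* geographically clustered community surveys: one over-sampled rectangle
  (emulating a region screened near-exhaustively while the rest of the
  country gets a sparse sample), binomial case counts with a logit-scale
  community nugget of variance τ²;
* an adult population surface and rectangular administrative polygons.

All outputs are pure functions of (config, seed).  Gaussian fields are
simulated exactly by Cholesky factorisation of the cell-to-cell
correlation matrix, which bounds worlds to ``MAX_EXACT_CELLS`` cells;
that ceiling is a deliberate design choice because exactness is what makes
parameter-recovery tests meaningful.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import expit, logit
from shapely.geometry import Polygon, box

from .raster import RasterGrid, RasterStack

__all__ = [
    "SyntheticWorldConfig",
    "TruthSurfaces",
    "MAX_EXACT_CELLS",
    "generate_covariates",
    "generate_truth",
    "simulate_surveys",
    "generate_population",
    "generate_admin",
]

#: exact-Cholesky grid-size ceiling (cells); larger worlds are refused.
MAX_EXACT_CELLS = 10_000


@dataclass
class SyntheticWorldConfig:
    """Parameters of one synthetic world.

    Defaults describe the study conditions the pipeline is exercised
    under: a 60×60 km country at 1 km resolution, five autocorrelated
    covariates, a prevalence field with a low intercept (endemic but rare
    disease), spatial variance σ²=1 over a 10 km range, a community-level
    nugget τ²=0.25, and 748 surveyed communities of which 90% fall inside
    one heavily screened rectangle — mirroring a national dataset
    dominated by a single intensively surveyed region.
    """

    grid_shape: tuple[int, int] = (60, 60)
    cell_size: float = 1.0  # km
    n_covariates: int = 5
    covariate_ranges: tuple[float, ...] = (20.0, 15.0, 10.0, 10.0, 5.0)
    beta: tuple[float, ...] = (-9.0, 3.5, -2.0, 1.2, 0.0, 0.0)
    sigma2: float = 1.0
    phi: float = 10.0  # km
    tau2: float = 0.25
    n_communities: int = 748
    oversample_region: tuple[float, float, float, float] = (0.0, 30.0, 30.0, 60.0)
    oversample_fraction: float = 0.9
    n_per_community_range: tuple[int, int] = (100, 500)
    suitability_floor: float = 0.0025
    seed: int = 0
    west: float = 0.0
    north: float = 60.0
    crs: str = "local-km"

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows * cols > MAX_EXACT_CELLS:
            raise ValueError(
                f"grid has {rows * cols} cells; exact GP simulation is capped at "
                f"{MAX_EXACT_CELLS} (use a smaller world)"
            )
        if self.sigma2 < 0 or self.tau2 < 0:
            raise ValueError("variances sigma2 and tau2 must be non-negative")
        if self.phi <= 0:
            raise ValueError("correlation range phi must be positive")
        if len(self.covariate_ranges) != self.n_covariates:
            raise ValueError("need one correlation range per covariate")
        if any(r < 0 for r in self.covariate_ranges):
            raise ValueError("covariate ranges must be non-negative")
        if len(self.beta) != self.n_covariates + 1:
            raise ValueError(
                f"beta must have length n_covariates+1 = {self.n_covariates + 1}"
            )
        xmin, ymin, xmax, ymax = self.oversample_region
        if not (
            self.west <= xmin < xmax <= self.west + cols * self.cell_size
            and self.north - rows * self.cell_size <= ymin < ymax <= self.north
        ):
            raise ValueError("oversample_region must lie inside the grid bounds")
        if not 0.0 <= self.oversample_fraction <= 1.0:
            raise ValueError("oversample_fraction must be in [0, 1]")
        lo, hi = self.n_per_community_range
        if not 1 <= lo <= hi:
            raise ValueError("n_per_community_range must satisfy 1 <= lo <= hi")

    def blank_grid(self) -> RasterGrid:
        rows, cols = self.grid_shape
        return RasterGrid(
            data=np.zeros((rows, cols)),
            west=self.west,
            north=self.north,
            cell=self.cell_size,
            crs=self.crs,
            mask=np.zeros((rows, cols), dtype=bool),
        )

    def rng(self, stage: str) -> np.random.Generator:
        """Stage-specific generator: seed ⊕ CRC32(stage), documented and stable."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        )


def strong_signal_config(seed: int = 0) -> "SyntheticWorldConfig":
    """A world whose ecology is sharply covariate-driven.

    Three strong covariate effects, no residual spatial process, a small
    community nugget, heavy screening effort, and a suitability floor
    matched to the detection limit of that effort (≈ ln 2 / n̄ screened).
    Used to measure how well the suitability ensemble can recover a truth
    that the covariates fully determine.
    """
    return SyntheticWorldConfig(
        grid_shape=(45, 45),
        n_covariates=3,
        covariate_ranges=(25.0, 15.0, 10.0),
        beta=(-10.0, 5.0, -3.0, 2.0),
        sigma2=0.0,
        phi=10.0,
        tau2=0.05,
        n_communities=400,
        oversample_region=(0.0, 22.5, 22.5, 45.0),
        oversample_fraction=0.7,
        n_per_community_range=(200, 800),
        suitability_floor=0.002,
        seed=seed,
        north=45.0,
    )


@dataclass
class TruthSurfaces:
    """The known truth of a synthetic world."""

    prevalence: RasterGrid       # p(x) in (0, 1)
    suitability: RasterGrid      # 1 where p(x) > floor
    spatial_effect: RasterGrid   # S(x), the GP realisation
    linear_predictor: RasterGrid # d(x)ᵀβ + S(x) on the logit scale


# --------------------------------------------------------------------- fields
def _cell_coords(config: SyntheticWorldConfig) -> np.ndarray:
    grid = config.blank_grid()
    X, Y = grid.cell_centers()
    return np.column_stack([X.ravel(), Y.ravel()])


def _exact_gaussian_field(
    coords: np.ndarray,
    corr_range: float,
    rng: np.random.Generator,
    chol_cache: dict[float, np.ndarray] | None = None,
) -> np.ndarray:
    """Unit-variance GP draw with exponential correlation exp(-d/range).

    range == 0 degenerates to iid noise.  A jitter of 1e-10 keeps the
    Cholesky factorisation stable for near-singular long-range fields.
    """
    n = len(coords)
    z = rng.standard_normal(n)
    if corr_range == 0.0:
        return z
    if chol_cache is not None and corr_range in chol_cache:
        L = chol_cache[corr_range]
    else:
        R = np.exp(-squareform(pdist(coords)) / corr_range)
        R[np.diag_indices(n)] += 1e-10
        L = np.linalg.cholesky(R)
        if chol_cache is not None:
            chol_cache[corr_range] = L
    return L @ z


def generate_covariates(config: SyntheticWorldConfig) -> RasterStack:
    """Simulate the covariate rasters.

    Each covariate is a stationary GP with its configured correlation
    range, standardised to mean 0 / unit variance over unmasked cells.
    Deterministic given the config seed; Cholesky factors are cached per
    distinct range.
    """
    coords = _cell_coords(config)
    grid = config.blank_grid()
    cache: dict[float, np.ndarray] = {}
    layers: dict[str, RasterGrid] = {}
    for i, corr_range in enumerate(config.covariate_ranges):
        rng = config.rng(f"covariate-{i}")
        f = _exact_gaussian_field(coords, corr_range, rng, cache)
        f = (f - f.mean()) / f.std()
        layers[f"cov{i}"] = grid.copy_with(f.reshape(config.grid_shape))
    return RasterStack(layers)


def generate_truth(stack: RasterStack, config: SyntheticWorldConfig) -> TruthSurfaces:
    """Build the true prevalence and suitability surfaces on the stack grid."""
    if not stack.grid.same_grid(config.blank_grid()):
        raise ValueError("covariate stack is not aligned with the config grid")
    beta = np.asarray(config.beta, dtype=float)
    if len(beta) != len(stack) + 1:
        raise ValueError(
            f"beta has length {len(beta)} but the stack carries {len(stack)} "
            "covariates (need n_covariates + 1 including the intercept)"
        )
    D = np.column_stack([np.ones(stack.grid.data.size), stack.feature_matrix()])
    eta_fixed = D @ beta
    if config.sigma2 > 0:
        coords = _cell_coords(config)
        S = np.sqrt(config.sigma2) * _exact_gaussian_field(
            coords, config.phi, config.rng("truth-gp")
        )
    else:
        S = np.zeros_like(eta_fixed)
    eta = eta_fixed + S
    p = expit(eta)
    shape = config.grid_shape
    grid = stack.grid
    return TruthSurfaces(
        prevalence=grid.copy_with(p.reshape(shape)),
        suitability=grid.copy_with((p > config.suitability_floor).astype(float).reshape(shape)),
        spatial_effect=grid.copy_with(S.reshape(shape)),
        linear_predictor=grid.copy_with(eta.reshape(shape)),
    )


# -------------------------------------------------------------------- surveys
def _region_mask(config: SyntheticWorldConfig) -> np.ndarray:
    """Boolean cell mask of the oversampled rectangle (by cell centre)."""
    grid = config.blank_grid()
    X, Y = grid.cell_centers()
    xmin, ymin, xmax, ymax = config.oversample_region
    return (X >= xmin) & (X < xmax) & (Y > ymin) & (Y <= ymax)


def simulate_surveys(truth: TruthSurfaces, config: SyntheticWorldConfig) -> pd.DataFrame:
    """Draw clustered community surveys with binomial case counts.

    Community locations are distinct cell centres: a configured fraction
    inside the oversampled rectangle, the rest outside.  Screening effort
    is Uniform(n_per_community_range); the community-level nugget z ~
    N(0, τ²) acts on the logit scale, cases ~ Binomial(n, logit⁻¹(logit p + z)).
    """
    if not truth.prevalence.same_grid(config.blank_grid()):
        raise ValueError("truth surfaces are not on the config grid")
    rng = config.rng("surveys")
    in_region = _region_mask(config).ravel()
    idx_in = np.flatnonzero(in_region)
    idx_out = np.flatnonzero(~in_region)
    n_in = int(round(config.oversample_fraction * config.n_communities))
    n_out = config.n_communities - n_in
    if n_in > len(idx_in) or n_out > len(idx_out):
        raise ValueError("not enough distinct cells for the requested communities")
    chosen = np.concatenate(
        [
            rng.choice(idx_in, size=n_in, replace=False),
            rng.choice(idx_out, size=n_out, replace=False),
        ]
    )
    rng.shuffle(chosen)

    grid = truth.prevalence
    X, Y = grid.cell_centers()
    x = X.ravel()[chosen]
    y = Y.ravel()[chosen]
    p = grid.data.ravel()[chosen]

    lo, hi = config.n_per_community_range
    n_screened = rng.integers(lo, hi + 1, size=config.n_communities)
    z = (
        np.sqrt(config.tau2) * rng.standard_normal(config.n_communities)
        if config.tau2 > 0
        else np.zeros(config.n_communities)
    )
    with np.errstate(divide="ignore"):
        eta = logit(np.clip(p, 1e-12, 1 - 1e-12))
    p_comm = np.where(p <= 0, 0.0, np.where(p >= 1, 1.0, expit(eta + z)))
    cases = rng.binomial(n_screened, p_comm)
    return pd.DataFrame(
        {
            "community_id": [f"c{i:04d}" for i in range(config.n_communities)],
            "x_km": x,
            "y_km": y,
            "n_screened": n_screened,
            "n_cases": cases,
        }
    )


# ---------------------------------------------------- population & admin units
def generate_population(
    config: SyntheticWorldConfig,
    total_population: float = 2_000_000.0,
    corr_range: float = 15.0,
) -> RasterGrid:
    """A smooth, everywhere-positive population-density surface.

    Log-Gaussian field scaled so the grid total equals ``total_population``
    — a caricature of a settlement surface (clustered but nowhere exactly
    zero), adequate for exercising the burden arithmetic.
    """
    coords = _cell_coords(config)
    f = _exact_gaussian_field(coords, corr_range, config.rng("population"))
    dens = np.exp(f)
    dens *= total_population / dens.sum()
    return config.blank_grid().copy_with(dens.reshape(config.grid_shape))


def generate_admin(
    config: SyntheticWorldConfig, nx: int = 2, ny: int = 2
) -> list[tuple[str, Polygon]]:
    """Partition the world into an nx × ny checkerboard of named regions."""
    rows, cols = config.grid_shape
    width = cols * config.cell_size
    height = rows * config.cell_size
    south = config.north - height
    out: list[tuple[str, Polygon]] = []
    for j in range(ny):
        for i in range(nx):
            poly = box(
                config.west + i * width / nx,
                south + j * height / ny,
                config.west + (i + 1) * width / nx,
                south + (j + 1) * height / ny,
            )
            out.append((f"region_{j}{i}", poly))
    return out
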
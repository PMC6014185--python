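"""Pipeline configuration: one TOML file, one master seed.

Every tunable of the mapping pipeline lives here with its study default:
500 background points, a 75% positive subsample in the over-represented
region, BRT learning rate 0.005 with interaction depth 4, 100 ensemble
replicates on 80/20 splits, AUC ≥ 0.8 / TSS ≥ 0.7 member selection, a 1%
prevalence exceedance threshold and 1000 predictive samples.  Any value a
user overrides away from these reference defaults is logged at startup so
a run's provenance is visible in its log.

Per-stage random generators derive from the master seed as
``SeedSequence([seed, crc32(stage_name)])`` — documented, stable, and
independently re-runnable per stage.
"""

from __future__ import annotations

import logging
import tomllib
import zlib
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np

__all__ = ["PipelineConfig", "load_config", "stage_rng", "stage_seed"]

log = logging.getLogger(__name__)

#: defaults fixed by the study design (logged when overridden)
REFERENCE_DEFAULTS = {
    "n_background": 500,
    "positive_fraction": 0.75,
    "brt_learning_rate": 0.005,
    "brt_interaction_depth": 4,
    "n_reps": 100,
    "train_frac": 0.8,
    "auc_min": 0.8,
    "tss_min": 0.7,
    "exceedance_threshold": 0.01,
}


@dataclass
class PipelineConfig:
    """All pipeline tunables plus synthetic-world parameters and paths."""

    # paths
    outdir: str = "podomap_run"

    # synthetic world
    grid_shape: tuple[int, int] = (60, 60)
    cell_size: float = 1.0
    n_covariates: int = 5
    covariate_ranges: tuple[float, ...] = (20.0, 15.0, 10.0, 10.0, 5.0)
    beta: tuple[float, ...] = (-9.0, 3.5, -2.0, 1.2, 0.0, 0.0)
    sigma2: float = 1.0
    phi: float = 10.0
    tau2: float = 0.25
    n_communities: int = 748
    oversample_region: tuple[float, float, float, float] = (0.0, 30.0, 30.0, 60.0)
    oversample_fraction: float = 0.9
    n_per_community_range: tuple[int, int] = (100, 500)
    suitability_floor: float = 0.0025
    total_population: float = 2_000_000.0
    adult_fraction: float = 0.55

    # background / weighting
    kde_bandwidth: float | None = None  # None -> Silverman's rule
    n_background: int = 500
    positive_fraction: float = 0.75

    # ensemble
    brt_learning_rate: float = 0.005
    brt_interaction_depth: int = 4
    brt_max_trees: int = 5000
    rf_trees: int = 500
    n_reps: int = 100
    train_frac: float = 0.8
    auc_min: float = 0.8
    tss_min: float = 0.7
    algorithms: tuple[str, ...] = ("brt", "rf")

    # geostatistics
    geostat_method: str = "mcml"
    geostat_mc: int = 500
    exceedance_threshold: float = 0.01
    n_samples: int = 1000

    # orchestration
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background < 1:
            raise ValueError("n_background must be >= 1")
        if not 0 < self.positive_fraction <= 1:
            raise ValueError("positive_fraction must be in (0, 1]")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        for name, ref in REFERENCE_DEFAULTS.items():
            val = getattr(self, name)
            if val != ref:
                log.info(
                    "config deviates from the study default: %s = %r (default %r)",
                    name, val, ref,
                )

    def as_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a TOML config; keys mirror :class:`PipelineConfig` field names."""
    raw = tomllib.loads(Path(path).read_text())
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    # TOML arrays arrive as lists; the dataclass stores tuples
    for key in (
        "grid_shape", "covariate_ranges", "beta", "oversample_region",
        "n_per_community_range", "algorithms",
    ):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage integer seed (< 2^31)."""
    ss = np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])
    )
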
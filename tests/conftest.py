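import numpy as np
import pandas as pd
import pytest

from podomap import synthdata as syn
from podomap import rasterops as ro
from podomap.raster import RasterGrid, RasterStack


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world shared by read-only tests."""
    cfg = syn.SyntheticWorldConfig(
        grid_shape=(30, 30),
        n_covariates=2,
        covariate_ranges=(12.0, 6.0),
        beta=(-5.5, 1.8, -1.0),
        sigma2=0.5,
        phi=8.0,
        tau2=0.1,
        n_communities=120,
        oversample_region=(0.0, 15.0, 15.0, 30.0),
        oversample_fraction=0.6,
        n_per_community_range=(100, 300),
        seed=11,
        north=30.0,
    )
    stack = syn.generate_covariates(cfg)
    truth = syn.generate_truth(stack, cfg)
    surveys = syn.simulate_surveys(truth, cfg)
    features = ro.extract_features(stack, surveys)
    return {
        "cfg": cfg,
        "stack": stack,
        "truth": truth,
        "surveys": surveys,
        "features": features,
    }


@pytest.fixture
def unit_grid():
    """A 10x10 all-valid grid on [0,10]x[0,10] km."""
    return RasterGrid(
        data=np.zeros((10, 10)),
        west=0.0,
        north=10.0,
        cell=1.0,
        mask=np.zeros((10, 10), dtype=bool),
    )


def make_grid(data, west=0.0, north=None, cell=1.0, mask=None):
    data = np.asarray(data, dtype=float)
    if north is None:
        north = data.shape[0] * cell
    return RasterGrid(data=data, west=west, north=north, cell=cell, mask=mask)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
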
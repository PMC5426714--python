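import numpy as np
import pytest
from hypothesis import settings

from anophrisk.config import ModelParams, default_weight_table
from anophrisk.pipeline import run_pipeline
from anophrisk.synth import ScenarioSpec

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def weights():
    return default_weight_table()


@pytest.fixture(scope="session")
def default_result():
    """One full pipeline run on the default synthetic scenario (seed 7)."""
    return run_pipeline(ScenarioSpec(seed=7))


@pytest.fixture
def small_spec():
    """A fast 40 x 40 km scenario for tests that rerun the generators."""
    return ScenarioSpec(seed=3, extent=(0, 0, 40_000, 40_000),
                        resolution_m=1000, n_districts=4, n_villages=60)


def random_dem(rng: np.random.Generator, n: int = 8, dx: float = 100.0):
    """Small random DEM for flow-routing oracles."""
    from anophrisk.raster import Raster
    return Raster(rng.uniform(0, 50, (n, n)), 0.0, n * dx, dx)
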
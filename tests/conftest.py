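import numpy as np
import pytest

from scrubcomfort import ComfortParams, GeneratorSpec, comfort_grid, stevens_grid


@pytest.fixture(scope="session")
def calibrated_params() -> ComfortParams:
    """The calibrated model constants (nylon brush, forearm)."""
    return ComfortParams()


@pytest.fixture(scope="session")
def calibration_grid():
    """The 64-condition Stevens calibration design, 10 s strokes."""
    return stevens_grid(dt=10.0)


@pytest.fixture(scope="session")
def surface_grid():
    """The 42-condition comfort calibration design."""
    return comfort_grid(dt=10.0)


@pytest.fixture()
def noiseless_surface_spec(surface_grid):
    return GeneratorSpec(grid=tuple(surface_grid), noise_sd=0.0, seed=123)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20221104)
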
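import numpy as np
import pytest

from kiwifusion.synth import (
    ExperimentDesign,
    SensorPanel,
    SpectralModelParams,
    TrajectoryParams,
    generate_experiment,
)


@pytest.fixture(scope="session")
def default_design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def small_design():
    return ExperimentDesign(day_offsets=(0, 5, 11, 20), fruits_per_day=4)


@pytest.fixture(scope="session")
def small_bundle(small_design):
    """A 16-fruit noisy experiment used across feature-level tests."""
    return generate_experiment(small_design, seed=11)


@pytest.fixture(scope="session")
def noise_free_bundle(small_design):
    params = SpectralModelParams(noise_sd=0.0, mismatch_sd=(0.0, 0.0, 0.0),
                                 day_mismatch_sd=0.0, pixel_noise_sd=0.0)
    panel = SensorPanel(noise_sd=0.0)
    return generate_experiment(
        small_design, TrajectoryParams().noise_free(), panel, params,
        seed=7, aroma_noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
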
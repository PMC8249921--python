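import numpy as np
import pytest

from cmcsim.emg import ElectrodePoint, FiringModel, MuscleModel


@pytest.fixture(scope="session")
def small_muscle() -> MuscleModel:
    """Reduced muscle for fast synthesis tests: same physics, ~1.6k fibers."""
    return MuscleModel(muscle_diameter=8.0, n_motor_units=16)


@pytest.fixture(scope="session")
def electrode() -> ElectrodePoint:
    return ElectrodePoint(0.0, 5.0, 30.0)


@pytest.fixture(scope="session")
def default_firing() -> FiringModel:
    return FiringModel(burst_window=(0.0, 3.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
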
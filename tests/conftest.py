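import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cahomeo import ModelParameters, Simulation
from cahomeo.calcium import CalciumParams


@pytest.fixture(scope="session")
def base_params():
    return ModelParameters.base()


@pytest.fixture(scope="session")
def passive_params():
    return ModelParameters.passive()


@pytest.fixture()
def passive_sim(passive_params):
    return Simulation(passive_params, dt=0.05)


@pytest.fixture()
def base_sim(base_params):
    return Simulation(base_params, dt=0.05)


@pytest.fixture(scope="session")
def base_measurements(base_params):
    """Seven intrinsic measurements of the hand-tuned base model (cached)."""
    from cahomeo.measurements import measure_all
    return measure_all(Simulation(base_params, dt=0.05))


@pytest.fixture(scope="session")
def calcium_params():
    return CalciumParams().resolved()
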
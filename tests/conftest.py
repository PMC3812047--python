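import numpy as np
import pytest
from hypothesis import settings

from protoadapt.config import (
    CellGeometry,
    DiffusionParams,
    ReceptorParams,
    SimulationConfig,
    SolverSettings,
    StepStimulus,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def geom() -> CellGeometry:
    return CellGeometry(radius=5.0, receptor_inner_length=0.5)


@pytest.fixture
def receptor() -> ReceptorParams:
    return ReceptorParams()


@pytest.fixture
def diffusion() -> DiffusionParams:
    return DiffusionParams()


@pytest.fixture
def step_config() -> SimulationConfig:
    return SimulationConfig(
        stimulus=StepStimulus(c0=1.0, c1=1.5, t_step=0.05),
        solver=SolverSettings(dt=1e-3, t_end=1.0),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231024)
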
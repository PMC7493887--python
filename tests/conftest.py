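import numpy as np
import pytest

from lysodyn.dynamics import (InductionRule, ModelParameters, SimulationState,
                              VIRULENT)


@pytest.fixture
def virulent_params():
    return ModelParameters(induction=InductionRule(mode=VIRULENT))


@pytest.fixture
def default_params():
    return ModelParameters()


@pytest.fixture
def moi10_init():
    """Coincubation at 1e5 cells/mL with tenfold more virus."""
    return SimulationState.from_per_ml(1e5, 1e6, 0.0)


@pytest.fixture
def week_grid():
    return np.linspace(0.0, 7.0, 29)


@pytest.fixture
def two_week_grid():
    return np.arange(0.0, 14.01, 0.25)
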
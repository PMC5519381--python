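import numpy as np
import pytest

from foldscale.models import Baselines, ThermoThreeState, ThermoTwoState
from foldscale.simulate import default_baselines, default_grid


@pytest.fixture
def grid():
    return default_grid()


@pytest.fixture
def two_state_truth():
    return ThermoTwoState(dG0=8.0, m=2.5)


@pytest.fixture
def three_state_truth():
    return ThermoThreeState(dG1=3.0, m1=1.5, dG2=5.0, m2=1.2)


@pytest.fixture
def baselines():
    return default_baselines()


@pytest.fixture
def baselines3():
    return default_baselines(three_state=True)
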
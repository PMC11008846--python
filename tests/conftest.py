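import pytest

from femrel.random_model import RandomVariable
from femrel.reliability import YieldCriterion
from femrel.response_surface import PUBLISHED_MODEL


@pytest.fixture
def model():
    """The published strain surrogate."""
    return PUBLISHED_MODEL


@pytest.fixture
def walking_scenario_vars():
    """BMD and loading variables for the 50-64 / normal-walking reference
    scenario at COV 0.1 for both inputs."""
    bmd = RandomVariable(mean=0.3375, sd=0.03375, label="bmd")
    bw = RandomVariable(mean=2.38, sd=0.238, label="bw")
    return bmd, bw


@pytest.fixture
def default_criterion():
    return YieldCriterion()
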
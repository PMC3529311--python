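import numpy as np
import pytest

from equiscale.cost_model import reference_cost_model
from equiscale.effectiveness_model import reference_effectiveness_model
from equiscale.scaleup import Scenario


@pytest.fixture(scope="session")
def cost_model():
    return reference_cost_model()


@pytest.fixture(scope="session")
def eff_model():
    return reference_effectiveness_model()


@pytest.fixture
def toy_pools():
    """Five-quintile toy: coverage .8/.6/.5/.4/.2, 1000 episodes each."""
    coverage = np.array([0.8, 0.6, 0.5, 0.4, 0.2])
    episodes = np.full(5, 1000.0)
    return coverage, episodes


@pytest.fixture
def toy_scenario():
    """Small fully-specified scenario with poorer quintiles carrying more
    burden (deaths and CFR non-decreasing Q1 -> Q5)."""
    return Scenario(
        country="toy",
        u5mr=(50.0, 80.0, 110.0, 150.0, 200.0),
        coverage=(0.8, 0.6, 0.5, 0.4, 0.2),
        episodes=(1000.0, 1000.0, 1000.0, 1000.0, 1000.0),
        pneumonia_deaths=(5.0, 10.0, 20.0, 40.0, 80.0),
        e_adj=(90.0, 85.0, 80.0, 70.0, 60.0),
        unit_cost=(1.0, 1.3, 1.6, 2.0, 2.5),
    )
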
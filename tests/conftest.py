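import numpy as np
import pytest

from autoshape.agents import AgentParams, FixedPointAgent, OracleAgent, make_cohort
from autoshape.config import default_config
from autoshape.engine import ScreenGeometry, TrialConfig, run_trial
from autoshape.pipeline import simulate
from autoshape.shaping import ShapingSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_trial_config():
    return TrialConfig(screen=ScreenGeometry(), shaping=ShapingSpec(0.3))


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced default cohort used by several analysis tests."""
    return default_config(n_participants=12, trials_per_function=6, seed=7)


@pytest.fixture(scope="session")
def small_log(small_cfg):
    return simulate(small_cfg)


@pytest.fixture
def oracle_trial(default_trial_config, rng):
    return run_trial(OracleAgent(), default_trial_config, rng)


@pytest.fixture
def never_reinforced_trial(default_trial_config, rng):
    # a screen corner is always > 400 px from any feasible center
    return run_trial(FixedPointAgent((0.0, 0.0)), default_trial_config, rng)


@pytest.fixture(scope="session")
def tiny_cohort():
    return make_cohort(AgentParams(), 3, np.random.default_rng(0))
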
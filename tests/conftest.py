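import numpy as np
import pytest

from screencea import synthetic_data as sd
from screencea.economics import CancerCareParams
from screencea.population_inputs import fit_age_curve


@pytest.fixture(scope="session")
def config():
    return sd.SyntheticConfig(seed=20260920)


@pytest.fixture(scope="session")
def life_table(config):
    return sd.make_life_table(config)


@pytest.fixture(scope="session")
def crc_params():
    return sd.crc_like_params()


@pytest.fixture(scope="session")
def eac_params():
    return sd.eac_like_params()


@pytest.fixture(scope="session")
def cost_curve(config):
    return fit_age_curve(sd.make_cost_observations(config), "exponential")


@pytest.fixture(scope="session")
def utility_curve(config):
    return fit_age_curve(sd.make_utility_observations(config), "linear", clip_unit=True)


@pytest.fixture(scope="session")
def care():
    return CancerCareParams()


@pytest.fixture(scope="session")
def small_cohort(crc_params, life_table):
    from screencea.natural_history import simulate_cohort

    return simulate_cohort(2000, crc_params, life_table, 1.0, seed=7, entry_age=40.0)


@pytest.fixture(scope="session")
def colonoscopy_50_75_10():
    return next(
        s for s in sd.default_strategy_grid("crc_like") if s.label == "Colonoscopy, 50-75, 10"
    )
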
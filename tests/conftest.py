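import numpy as np
import pytest

from boxcea.costing import PatientCostParams, default_price_table
from boxcea.synthetic_data import (apply_mitt_filter, default_config,
                                   generate_trial, records_to_frame)


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def prices():
    return default_price_table()


@pytest.fixture(scope="session")
def params():
    return PatientCostParams()


@pytest.fixture(scope="session")
def trial(config):
    """One analysed (post-mITT) synthetic trial, fixed seed."""
    return apply_mitt_filter(generate_trial(config, seed=42))


@pytest.fixture(scope="session")
def trial_frame(trial):
    return records_to_frame(trial)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
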
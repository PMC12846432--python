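import numpy as np
import pytest
from hypothesis import settings

import ehtkit as ek

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_trial():
    """One simulated 7-arm trial at the default conditions, 7 rounds."""
    return ek.simulate_trial(ek.default_config(seed=11, rounds=7))


@pytest.fixture(scope="session")
def small_trial_totals(small_trial):
    return small_trial.all_arm_totals()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
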
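import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from oncomir.synthetic import SyntheticConfig, generate_cohort

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


SMALL_GROUPS = {
    ("control", "control"): 10,
    ("DLBCL", "systemic"): 20,
    ("DLBCL", "SCNSL"): 12,
}


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=7, group_sizes=SMALL_GROUPS)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def noiseless_cohort():
    cfg = SyntheticConfig(
        seed=11, group_sizes=SMALL_GROUPS, ct_noise_sd=0.0,
        sd_log2={"CSF": 0.0, "plasma": 0.0},
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)
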
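import numpy as np
import pytest

import twintraj as tt


@pytest.fixture(scope="session")
def default_cohort():
    """Small study-analogue cohort shared across read-only tests."""
    return tt.simulate_cohort(tt.default_config(seed=11))


@pytest.fixture(scope="session")
def ae_cohort():
    """Single-trait AE cohort (a2 = 0.7) with MZ and DZ male groups."""
    cfg = tt.single_trait_config(0.7, n_pairs=1000, groups=("MZM", "DZM"), seed=21)
    return tt.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def ae_groups(ae_cohort):
    return tt.twin_groups_from_table(ae_cohort.traits, "trait")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
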
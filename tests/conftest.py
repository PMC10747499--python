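import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mapbpk.parameters import VD_CORRECTION, cabotegravir
from mapbpk.physiology import generate_human_cohort, generate_rat_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rat():
    """One fixed-weight rat (no inter-animal variability)."""
    return generate_rat_cohort(1, 0.241, 0.0, seed=7)[0]


@pytest.fixture(scope="session")
def human_cohort_small():
    return generate_human_cohort(6, female_fraction=0.5, seed=11)


@pytest.fixture
def rat_map(rat):
    import copy

    s = copy.copy(rat)
    s.vd_correction = VD_CORRECTION[("rat", "MAP")]
    return s, cabotegravir("rat", "MAP")


@pytest.fixture
def rat_im(rat):
    import copy

    s = copy.copy(rat)
    s.vd_correction = VD_CORRECTION[("rat", "IM")]
    return s, cabotegravir("rat", "IM")
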
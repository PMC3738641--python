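import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import synoclass as sc

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort at the study group sizes (n = 93)."""
    return sc.generate_cohort(sc.default_config(), seed=1)


@pytest.fixture(scope="session")
def default_profiles(default_cohort):
    return sc.profile_cohort(default_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-group cohort with 8 samples per group (fast downstream runs)."""
    cfg = sc.default_config()
    cfg.group_sizes = {g: 8 for g in sc.GROUPS}
    return sc.generate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    return sc.profile_cohort(small_cohort)


def make_cohort(rows):
    """Cohort from (sample_id, group, cd15, cd68, cd3, cd20, cd38) tuples."""
    df = pd.DataFrame(rows, columns=list(sc.data_model.COHORT_COLUMNS))
    return sc.Cohort(df)


@pytest.fixture
def toy_two_group_cohort():
    """Two groups of three identical-composition samples with a 2x TIC
    contrast (relative compositions equal, absolute scaled)."""
    rows = []
    for i in range(3):
        rows.append((f"ra{i}", "RA", 20.0, 40.0, 30.0, 6.0, 4.0))
        rows.append((f"oa{i}", "OA", 10.0, 20.0, 15.0, 3.0, 2.0))
    return make_cohort(rows)
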
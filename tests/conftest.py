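import numpy as np
import pandas as pd
import pytest

from morphnet.synthetic import GroundTruth, gen_gmv_parcels, gen_subject_table


@pytest.fixture(scope="session")
def small_cohort():
    """40 patients + 40 controls with the default planted effects."""
    truth = GroundTruth.paper_like(seed=11)
    subjects = gen_subject_table(40, 40, seed=11)
    gmv = gen_gmv_parcels(subjects, truth)
    return subjects, gmv, truth


@pytest.fixture(scope="session")
def null_cohort():
    """30/30 cohort with no planted effects of any kind."""
    truth = GroundTruth(seed=23)
    subjects = gen_subject_table(30, 30, seed=23)
    gmv = gen_gmv_parcels(subjects, truth)
    return subjects, gmv, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_groups(n_a, n_b):
    return pd.DataFrame({"group": ["patient"] * n_a + ["control"] * n_b})
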
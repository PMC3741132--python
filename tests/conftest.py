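import numpy as np
import pytest

from ocm_ann import synthetic_cohort as sc
from ocm_ann.cohort_model import load_default_panel


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def marginals():
    return sc.table1_marginals()


@pytest.fixture(scope="session")
def cohort40(marginals, panel):
    """A 40+40 synthetic cohort mirroring the study design."""
    ad, control = marginals
    return sc.generate_cohort(ad, control, n_per_group=40, seed=11, panel=panel)


@pytest.fixture(scope="session")
def big_cohort(marginals, panel):
    """Large cohort for marginal-recovery checks (shared across tests)."""
    ad, control = marginals
    return sc.generate_cohort(ad, control, n_per_group=10_000, seed=3, panel=panel)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
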
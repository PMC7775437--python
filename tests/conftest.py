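import pytest

from readclock import default_sim_panel, simulate_cohort


@pytest.fixture(scope="session")
def sim_panel():
    return default_sim_panel()


@pytest.fixture(scope="session")
def train_cohort(sim_panel):
    """Training cohort at the study's scale: 24 mice, 2,000 reads/amplicon."""
    return simulate_cohort(sim_panel, n_mice=24, seed=11, id_prefix="T")


@pytest.fixture(scope="session")
def val_cohort(sim_panel):
    """Independent validation cohort: 21 mice."""
    return simulate_cohort(sim_panel, n_mice=21, seed=12, id_prefix="V")


@pytest.fixture(scope="session")
def train_matrix(train_cohort):
    return train_cohort.beta_matrix()


@pytest.fixture(scope="session")
def val_matrix(val_cohort):
    return val_cohort.beta_matrix()
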
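import pytest

from spongecerna.synthetic import SimParams, simulate_cohort

SMALL = dict(
    n_low=40, n_high=30, n_mrna=300, n_lncrna=100, n_mirna=60,
    n_triplets=12, n_prognostic_hubs=4, seed=11,
)


@pytest.fixture(scope="session")
def small_params():
    return SimParams(**SMALL)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    """One small synthetic cohort shared across the unit-test session."""
    return simulate_cohort(small_params)
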
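import numpy as np
import pytest

import petct_radiomics as pr


@pytest.fixture(scope="session")
def small_cohort():
    """12-patient cohort with moderate effects, shared across tests."""
    return pr.generate_cohort(pr.CohortSpec(n_patients=12, seed=7))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return pr.cohort_to_table(small_cohort)


@pytest.fixture(scope="session")
def calibration_cohort():
    """200-patient null cohort used for marginal-calibration checks."""
    return pr.generate_cohort(pr.null_spec(n_patients=200, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
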
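import numpy as np
import pytest

import raschmon as rm


@pytest.fixture(scope="session")
def default_bank():
    """The 25-item sum-zero default difficulty bank."""
    return np.array(list(rm.DEFAULT_ITEM_BANK.values()))


@pytest.fixture(scope="session")
def two_item_matrix():
    """Closed-form CML case: 20 persons score (1,0), 10 score (0,1)."""
    resp = np.array([[1, 0]] * 20 + [[0, 1]] * 10)
    ids = [f"R{i:03d}" for i in range(30)]
    return rm.ResponseMatrix(ids, ["V1", "V2"], resp)


@pytest.fixture(scope="session")
def simulated_cohort(default_bank):
    """A 197 x 25 cohort drawn from the default bank, fixed seed."""
    return rm.simulate_responses(
        rm.SimulationConfig(n_persons=197, item_difficulties=default_bank, seed=42)
    )


@pytest.fixture(scope="session")
def calibrated(simulated_cohort):
    items = rm.fit_cml(simulated_cohort.matrix)
    persons = rm.estimate_person_parameters(simulated_cohort.matrix, items)
    return simulated_cohort.matrix, items, persons
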
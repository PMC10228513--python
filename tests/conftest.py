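import numpy as np
import pandas as pd
import pytest

import hypoestimand as he


def make_dataset(rows: dict, k: int = 1, validate: bool = True) -> he.TrialDataset:
    return he.TrialDataset(pd.DataFrame(rows), k_ice_times=k, validate=validate)


@pytest.fixture(scope="session")
def toy_k1() -> he.TrialDataset:
    """Hand-sized K=1 dataset with ICEs and missing post-ICE outcomes."""
    return make_dataset(
        {
            "id": ["a", "b", "c", "d", "e", "f"],
            "L0": [7.2, 8.1, 8.9, 7.7, 8.4, 9.0],
            "A0": [0, 0, 0, 1, 1, 1],
            "L1": [7.5, 8.6, 9.4, 7.1, 8.0, 9.2],
            "A1": [0, 0, 1, 0, 0, 1],
            "Y": [7.4, 8.8, np.nan, 6.9, 7.9, 8.8],
        }
    )


@pytest.fixture(scope="session")
def sim_k1() -> he.TrialDataset:
    return he.simulate_trial(he.builtin_scenario("rescue_k1", n=300, seed=101))


@pytest.fixture(scope="session")
def sim_k2() -> he.TrialDataset:
    return he.simulate_trial(he.builtin_scenario("rescue_k2", n=400, seed=202))
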
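import numpy as np
import pandas as pd
import pytest

import conngrad as cg


@pytest.fixture(scope="session")
def scheme100():
    return cg.make_parcellation(100, 7, 4, seed=1)


@pytest.fixture(scope="session")
def scheme60():
    return cg.make_parcellation(60, 7, 4, seed=2)


@pytest.fixture(scope="session")
def truth100(scheme100):
    return cg.make_ground_truth(scheme100, n_affected=10, effect_size=1.0, seed=7)


@pytest.fixture(scope="session")
def fc_cohort(scheme100, truth100):
    """Small planted-effect functional cohort shared across tests."""
    study, _ = cg.simulate_fc_cohort(scheme100, 10, 10, truth100)
    return study


def covariates_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": [r.group for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "site": [r.site for r in records],
            "motion": [r.motion for r in records],
        }
    )


def random_spd_affinity(rng: np.random.Generator, p: int) -> np.ndarray:
    """A random symmetric non-negative connected affinity with unit diagonal."""
    w = rng.random((p, p))
    w = (w + w.T) / 2
    w += 0.05  # strictly positive => connected
    np.fill_diagonal(w, 1.0)
    return w
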
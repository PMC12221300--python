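import warnings

import numpy as np
import pytest

from gazeddm.diagnostics import prepare_trials
from gazeddm.inference import HierarchicalDDM, MCMCConfig
from gazeddm.synthetic import CohortConfig, gen_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """Small DDM-generated cohort shared across tests."""
    cfg = CohortConfig(model="DDM", n_participants=6, n_trials=50)
    trials, fixations, ratings, truth = gen_dataset(cfg, seed=42)
    return {"config": cfg, "trials": trials, "fixations": fixations,
            "ratings": ratings, "truth": truth}


@pytest.fixture(scope="session")
def oriented_small(small_cohort):
    oriented, report = prepare_trials(small_cohort["trials"], small_cohort["fixations"])
    return oriented


@pytest.fixture(scope="session")
def ddm_fit(oriented_small):
    """A short hierarchical DDM fit reused by diagnostics tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = HierarchicalDDM(model="DDM", config=MCMCConfig(3, 1500, 750, 2),
                              random_state=7).fit(oriented_small)
    return est.result_


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
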
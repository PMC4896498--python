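import logging
import warnings

import numpy as np
import pytest

import longbatch as lb
from longbatch.containers import GROUP

logging.disable(logging.WARNING)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def replicate_ds():
    """Default-scale replicate dataset: Table-style design, 2,000 probes."""
    return lb.simulate_dataset(lb.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_replicate_ds():
    """Cheap replicate dataset for unit tests (300 probes)."""
    return lb.simulate_dataset(
        lb.SimulationConfig(n_probes=300, n_negative_controls=40, seed=2))


@pytest.fixture(scope="session")
def cohort_ds():
    return lb.simulate_cohort(
        lb.SimulationConfig(n_subjects=60, n_probes=400,
                            n_negative_controls=40, seed=3))


def replicate_groups(meta):
    bl = meta.index[meta[GROUP] == "BL_rep"]
    fu = meta.index[meta[GROUP] == "BLFU_rep"]
    return bl, fu


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
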
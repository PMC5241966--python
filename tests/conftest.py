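import numpy as np
import pytest

import pdcaresim as pc


@pytest.fixture(scope="session")
def params():
    """The calibrated default fixture for the study Trust."""
    return pc.default_parameters()


@pytest.fixture(scope="session")
def scenarios():
    return pc.default_scenarios()


@pytest.fixture(scope="session")
def timed_baseline(params, scenarios):
    """The full 100-replication baseline experiment, with wall time."""
    import time

    start = time.perf_counter()
    results = pc.run_experiment(params, scenarios["baseline"])
    return results, time.perf_counter() - start


@pytest.fixture(scope="session")
def baseline_results(timed_baseline):
    return timed_baseline[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
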
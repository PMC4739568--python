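import numpy as np
import pytest

import divestate as ds


@pytest.fixture(scope="session")
def short_scenario():
    """Razorbill-like scenario kept short for unit tests."""
    return ds.razorbill_like(duration_h=0.3)


@pytest.fixture(scope="session")
def short_deployment(short_scenario):
    dep, truth = ds.simulate_deployment(short_scenario, seed=42)
    return dep, truth


@pytest.fixture(scope="session")
def short_features(short_scenario, short_deployment):
    dep, _ = short_deployment
    return ds.build_feature_table(dep, short_scenario.feature_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
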
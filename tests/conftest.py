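import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from netprio.synthdata import SimConfig, load_fixture

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table2() -> pd.DataFrame:
    return load_fixture("table2")


@pytest.fixture
def small_config() -> SimConfig:
    return SimConfig(seed=11, n_genes=200, n_features_metab=80, graph_n_nodes=30)
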
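import pytest
from hypothesis import settings

from shadownoise import (RateParameters, SystemConfig, build_network,
                         make_kruppel_config)

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def kruppel_network():
    return build_network(make_kruppel_config())


@pytest.fixture(scope="session")
def table1_params():
    return RateParameters()


@pytest.fixture(scope="session")
def single_t1_config(table1_params):
    return SystemConfig(enhancers=((1, 0),), params=table1_params)
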
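import numpy as np
import pytest

from nclandscape import (
    DistributionSpec,
    FibonacciGPMap,
    build_nc_graph,
    decompose_into_ncs,
)


@pytest.fixture(scope="session")
def fib3_map():
    return FibonacciGPMap(length=3)


@pytest.fixture(scope="session")
def fib3_labeling(fib3_map):
    return decompose_into_ncs(fib3_map)


@pytest.fixture(scope="session")
def fib3_graph(fib3_map, fib3_labeling):
    return build_nc_graph(fib3_map, fib3_labeling)


@pytest.fixture(scope="session")
def fib8_graph():
    m = FibonacciGPMap(length=8)
    return build_nc_graph(m, decompose_into_ncs(m))


@pytest.fixture(scope="session")
def uniform_dist():
    return DistributionSpec("uniform01")


@pytest.fixture(scope="session")
def exp_dist():
    return DistributionSpec("exponential", rate=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
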
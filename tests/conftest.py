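import numpy as np
import pytest

from rbottleneck import (and_gate, bsc_gate, build_joint, copy_gate,
                         spin_overlap_gate, unique_gate)


@pytest.fixture(scope="session")
def unique_system():
    return unique_gate()


@pytest.fixture(scope="session")
def and_system():
    return and_gate()


@pytest.fixture(scope="session")
def bsc_system():
    return bsc_gate()


@pytest.fixture(scope="session")
def spin_system():
    return spin_overlap_gate()


@pytest.fixture(scope="session")
def unique_joint(unique_system):
    return build_joint(unique_system)


@pytest.fixture(scope="session")
def and_joint(and_system):
    return build_joint(and_system)


@pytest.fixture(scope="session")
def bsc_joint(bsc_system):
    return build_joint(bsc_system)


@pytest.fixture(scope="session")
def spin_joint(spin_system):
    return build_joint(spin_system)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
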
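import logging

import pytest

import hillchain as hc

logging.getLogger("hillchain").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small1():
    """Small muscle, single CE, 2 ms quick release."""
    return hc.simulate(hc.build_chain(hc.SMALL, 1), 2e-3)


@pytest.fixture(scope="session")
def small16():
    return hc.simulate(hc.build_chain(hc.SMALL, 16), 2e-3)


@pytest.fixture(scope="session")
def small32():
    return hc.simulate(hc.build_chain(hc.SMALL, 32), 2e-3)


@pytest.fixture(scope="session")
def big1():
    """Big muscle, single CE, through the effective-mass pole."""
    return hc.simulate(hc.build_chain(hc.BIG, 1), 60e-3)


@pytest.fixture(scope="session")
def big32():
    return hc.simulate(hc.build_chain(hc.BIG, 32), 60e-3)
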
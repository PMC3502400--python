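"""Shared fixtures.

The closed-loop 30 s scenario runs are the expensive part of the suite, so
each published scenario is integrated once per session and shared by all
tests that read it.
"""

import numpy as np
import pytest

import gliovasc as gv
from gliovasc.simulator import short_pulse_protocol


@pytest.fixture(scope="session")
def params():
    return gv.ModelParams()


@pytest.fixture(scope="session")
def library():
    return gv.scenario_library()


def _run(name):
    cfg = gv.scenario_library()[name]
    return gv.run_simulation(cfg, gv.ModelParams())


@pytest.fixture(scope="session")
def continuous_run():
    return _run("continuous")


@pytest.fixture(scope="session")
def pulse_run():
    return _run("pulse")


@pytest.fixture(scope="session")
def subthreshold_run():
    return _run("subthreshold")


@pytest.fixture(scope="session")
def bursting_run():
    return _run("bursting")


@pytest.fixture(scope="session")
def vasomotion_run():
    return _run("vasomotion")


@pytest.fixture(scope="session")
def short_pulse_run():
    return gv.run_simulation(short_pulse_protocol(), gv.ModelParams())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
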
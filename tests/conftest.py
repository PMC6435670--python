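"""Shared fixtures: default synthetic pressure waves and steady-state beats.

Session-scoped so the (cheap but repeated) generation/simulation pipeline runs
once per test session.
"""

import numpy as np
import pytest

import bcgsim as b


@pytest.fixture(scope="session")
def gen_params():
    return b.BPGeneratorParams()


@pytest.fixture(scope="session")
def bp_set(gen_params):
    return b.generate_bp_set(gen_params)


@pytest.fixture(scope="session")
def geometry():
    return b.AortaGeometry()


@pytest.fixture(scope="session")
def body():
    return b.BodyParameters()


@pytest.fixture(scope="session")
def system(body):
    return b.assemble(body)


@pytest.fixture(scope="session")
def steady_beat(bp_set, geometry, body):
    return b.simulate_steady_beat(bp_set, geometry, body)


@pytest.fixture(scope="session")
def beat_fiducials(steady_beat):
    return b.detect_beat_waves(steady_beat)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
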
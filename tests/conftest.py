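import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_net():
    from growthnet.reference import make_reference_tracer

    return make_reference_tracer()


@pytest.fixture(scope="session")
def curve_oracle_gates():
    from growthnet.gates import OracleGates

    return OracleGates("curve")


@pytest.fixture(scope="session")
def object_oracle_gates():
    from growthnet.gates import OracleGates

    return OracleGates("object")


@pytest.fixture(scope="session")
def small_curve_stimulus():
    from growthnet.stimuli import generate_curve_pair

    return generate_curve_pair(12, 4, rng_seed=7)


def greedy_action(q):
    flat = int(np.argmax(q))
    r, c = np.unravel_index(flat, q.shape)
    return int(r), int(c)
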
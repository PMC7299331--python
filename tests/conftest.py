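import pytest
from hypothesis import HealthCheck, settings

from fibercircuits import DriveSignal, DynamicsSpec, make_circuit

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def ffl():
    return make_circuit("FFL")


@pytest.fixture
def sat_fff():
    return make_circuit("SAT_FFF")


@pytest.fixture
def unsat_fff():
    return make_circuit("UNSAT_FFF")


@pytest.fixture
def ffl_spec():
    """Parameter set under which the FFL converges to y = 0.6, z = 0.42."""
    return DynamicsSpec(
        alpha=0.2, gamma={"X": 0.12, "Y": 0.7}, k={"X": 0.5, "Y": 0.1}
    )


@pytest.fixture
def sat_fff_spec():
    return DynamicsSpec(
        alpha=0.06, gamma={"X": 0.775, "Y": 0.775}, k={"X": 0.5, "Y": 0.1}
    )


@pytest.fixture
def unsat_fff_spec():
    """Just inside the oscillatory phase: lambda ~ 1.0054."""
    return DynamicsSpec(
        alpha=0.205, gamma={"X": 0.454, "Y": 0.454}, k={"X": 0.5, "Y": 1.0}
    )


@pytest.fixture
def constant_x():
    return {"X": DriveSignal("constant", level=1.0)}
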
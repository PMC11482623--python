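import numpy as np
import pytest

from rtswitch import KineticModel
from rtswitch.quantify import TranscriptLadder
from rtswitch.switchsim import TSO, SwitchParams


@pytest.fixture(scope="session")
def datp_model() -> KineticModel:
    """Three-step adenosine-addition model (measured rates/amplitudes)."""
    return KineticModel([0.19, 0.61, 0.20], [0.96, 0.96, 0.86])


@pytest.fixture(scope="session")
def dgtp_model() -> KineticModel:
    """Two-step guanosine-addition model (measured rates/amplitudes)."""
    return KineticModel([0.035, 0.040], [0.94, 0.80])


@pytest.fixture(scope="session")
def default_params() -> SwitchParams:
    return SwitchParams()


@pytest.fixture(scope="session")
def blocked_tso() -> TSO:
    return TSO("CTCCTCTTCCTCCTCTTT", "DNA", True, "abasic_x5")


@pytest.fixture(scope="session")
def unblocked_tso() -> TSO:
    return TSO("CTCCTCTTCCTCCTCTTT", "DNA", False, "none")


@pytest.fixture
def small_ladder() -> TranscriptLadder:
    return TranscriptLadder(
        ["tx1", "tx2", "tx3"],
        np.array([500, 1000, 2000]),
        np.array([1.0, 10.0, 100.0]),
        ["ercc_like"] * 3,
        sequences=["ACGT" * 125, "ACGT" * 250, "ACGT" * 500],
    )


def random_valid_model(rng: np.random.Generator, n_steps=None) -> KineticModel:
    """Draw a random valid kinetic model (log-uniform rates, open fractions)."""
    n = int(n_steps or rng.integers(1, 4))
    k = 10.0 ** rng.uniform(-2, 1, size=n)
    a = rng.uniform(0.3, 1.0, size=n)
    return KineticModel(k, a)
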
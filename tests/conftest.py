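import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# residual warnings are expected under simulated noise; keep test output clean
logging.getLogger("midtrace").setLevel(logging.ERROR)
logging.getLogger("midtrace.correction").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def registry():
    from midtrace.registry import default_registry

    return default_registry()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_formula(rng, max_c: int = 12):
    """Random plausible fragment formula with at least one carbon."""
    from midtrace.chem import ElementalFormula

    counts = {
        "C": int(rng.integers(1, max_c + 1)),
        "H": int(rng.integers(0, 30)),
        "N": int(rng.integers(0, 3)),
        "O": int(rng.integers(0, 7)),
        "Si": int(rng.integers(0, 3)),
        "S": int(rng.integers(0, 2)),
    }
    return ElementalFormula(counts)


def random_mid(rng, n: int):
    """Random MID over m+0..m+n (Dirichlet, sums to 1)."""
    return rng.dirichlet(np.ones(n + 1))
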
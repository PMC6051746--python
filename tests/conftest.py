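import numpy as np
import pytest
from hypothesis import settings

from neurodiv import CycleTiming, ModeFractions, PopulationState

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def control_dorsal() -> ModeFractions:
    """Division-mode fractions of the control dorsal neural tube."""
    return ModeFractions(0.663, 0.259, 0.078)


@pytest.fixture
def control_ventral() -> ModeFractions:
    """Division-mode fractions of the control ventral neural tube."""
    return ModeFractions(0.293, 0.58, 0.127)


@pytest.fixture
def timing_12h() -> CycleTiming:
    return CycleTiming(tc_hours=12.0)


@pytest.fixture
def seed_population() -> PopulationState:
    return PopulationState(progenitors=100.0, neurons=100.0, time=0.0)


def rk4_oracle(p0, n0, g, eta, t, n_steps=20000):
    """Classic fixed-step RK4 on dP = g*eta*P, dN = (1-g)*eta*P.

    Independent of the closed form; used as the numerical oracle.
    """
    h = t / n_steps
    p, n = float(p0), float(n0)

    def deriv(p):
        return g * eta * p, (1 - g) * eta * p

    for _ in range(n_steps):
        k1p, k1n = deriv(p)
        k2p, k2n = deriv(p + h / 2 * k1p)
        k3p, k3n = deriv(p + h / 2 * k2p)
        k4p, k4n = deriv(p + h * k3p)
        p += h / 6 * (k1p + 2 * k2p + 2 * k3p + k4p)
        n += h / 6 * (k1n + 2 * k2n + 2 * k3n + k4n)
    return p, n
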
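import numpy as np
import pytest
from hypothesis import settings

from spinrelax import FieldContext, SpinSystem

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def spin_n15() -> SpinSystem:
    return SpinSystem()


@pytest.fixture(scope="session")
def field_750() -> FieldContext:
    return FieldContext(750.0)


@pytest.fixture(scope="session")
def field_700() -> FieldContext:
    return FieldContext(700.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def flat_high_freq_j(j0: float, jwx: float, jh: float, omega_x: float):
    """Spectral density flat across the three proton-frequency combinations,
    as assumed by the reduced mapping."""

    def j(w):
        w = np.atleast_1d(np.asarray(w, float))
        out = np.where(w == 0.0, j0, np.where(np.isclose(w, omega_x), jwx, jh))
        return out

    return j
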
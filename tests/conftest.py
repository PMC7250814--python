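import numpy as np
import pytest

from stateresp import model_zoo


@pytest.fixture
def panic_unit():
    """Panic model with every fast rate equal to one."""
    return model_zoo.panic(1.0, 1.0, 1.0, 1.0)


@pytest.fixture
def starvation_ref():
    """Starvation model with the reference type-III parameter set."""
    return model_zoo.starvation(
        c1=10.0, c2=0.2, d1=4.0, d2=3.0,
        Gamma1=10.0, Gamma2=2.0, delta1=0.2, delta2=0.5,
    )


@pytest.fixture
def two_state_up():
    """Two-state prey ladder, attack rates increasing with exposure (c1 < c2)."""
    return model_zoo.two_state_prey(A12=2.0, A1=0.5, c1=10.0, c2=15.0, d=1.0)


@pytest.fixture
def two_state_down():
    """Two-state prey ladder with c1 > c2 (response decreasing in Y)."""
    return model_zoo.two_state_prey(A12=2.0, A1=0.5, c1=20.0, c2=10.0, d=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
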
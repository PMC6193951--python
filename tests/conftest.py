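import numpy as np
import pytest

from chexfit.exchange import ExchangeModelSpec, ExchangeTopology, FieldContext


@pytest.fixture(scope="session")
def field600():
    return FieldContext(600.0)


@pytest.fixture(scope="session")
def field800():
    return FieldContext(800.0)


@pytest.fixture(scope="session")
def two_state_slow(field600):
    """Two-state exchange in the CEST-sensitive regime with resolved dips."""
    return ExchangeModelSpec.two_state(
        k_ex=120.0, p_E=0.048, delta_G_ppm=120.0, dw_ppm=2.0, r1=1.2, r2=11.0
    )


@pytest.fixture(scope="session")
def three_state_resolved():
    """Linear G<=>E1<=>E2 model slow enough that all three dips resolve."""
    return ExchangeModelSpec.three_state(
        ExchangeTopology.THREE_G_E1_E2,
        p_E1=0.06,
        p_E2=0.02,
        kex_1=60.0,
        kex_2=80.0,
        shifts_ppm=[119.0, 123.0, 115.0],
        r1=1.2,
        r2=11.0,
    )


@pytest.fixture(scope="session")
def cest_grid():
    return np.linspace(100.0, 138.0, 191)
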
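import numpy as np
import pytest

from grcube.equilibrium import EquilibriumParams, Milieu, ResponseSpec


@pytest.fixture
def unit_params():
    """All occupancy products and cooperativities equal to 1."""
    return EquilibriumParams(Ka=1e9, Kc=1e9, Kd=1e9)


@pytest.fixture
def unit_milieu():
    """Ka*L = Kc*C = Kd*D = 1 for unit_params."""
    return Milieu(L=1e-9, C=1e-9, D=1e-9, Rtot=1.0)


@pytest.fixture
def default_spec():
    return ResponseSpec()


def random_params(rng: np.random.Generator) -> EquilibriumParams:
    """Log-uniform draw over the regime the model is exercised in."""
    Ka, Kc, Kd = 10.0 ** rng.uniform(6, 10, 3)
    a, b, g, d = 10.0 ** rng.uniform(-3, 3, 4)
    return EquilibriumParams(Ka=Ka, Kc=Kc, Kd=Kd, alpha=a, beta=b, gamma=g, delta=d)


def random_milieu(rng: np.random.Generator) -> Milieu:
    L, C, D = 10.0 ** rng.uniform(-12, -5, 3)
    return Milieu(L=L, C=C, D=D, Rtot=float(10.0 ** rng.uniform(-2, 2)))
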
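import numpy as np
import pytest

from lacscape import Genotype, ModelParams


@pytest.fixture
def params():
    """Package defaults: eta on with theta = 0."""
    return ModelParams()


@pytest.fixture
def params_eta_off():
    return ModelParams(eta_enabled=False)


@pytest.fixture
def quadratic_setup():
    """Transport-cost-only configuration whose growth map is G(lam) = 1 - 0.21/lam.

    With eta off, c_delta = c_C = 0, c_T = 0.21 and a constitutive genotype of
    delta_max = 1 at E = E_norm (per-pump rate 1), the fixed points are the
    roots of lam**2 - lam + 0.21: 0.7 (stable) and 0.3 (unstable).
    """
    p = ModelParams(eta_enabled=False, c_delta=0.0, c_T=0.21, c_C=0.0)
    g = Genotype(1.0, 1.0, 1.0)
    return p, g, 1.0  # params, genotype, E


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
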
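import numpy as np
import pytest

from asdscreen.activity_model import Component, ModelConfig
from asdscreen.fixtures import (
    FixtureSpec,
    gen_analytic_system,
    gen_gaussian_profile,
    gen_segment_set,
)


@pytest.fixture
def tight_config():
    """Model configuration tight enough for derivative-based checks."""
    return ModelConfig(gamma_tol=1e-12, gamma_maxiter=10000)


@pytest.fixture
def small_cavity():
    return gen_segment_set(FixtureSpec(seed=7, n_segments=24, n_units=3, atoms_per_unit=2))


@pytest.fixture
def api_polymer_pair():
    """A synthetic API + polymer pair with HB surface and realistic sizes."""
    p_api = gen_gaussian_profile(
        "api", 250.0, 280.0,
        [("nhb", 0.002, 0.004, 0.6), ("oh", -0.012, 0.003, 0.2), ("oh", 0.013, 0.003, 0.2)],
    )
    p_poly = gen_gaussian_profile(
        "poly", 9000.0, 11000.0,
        [("nhb", -0.003, 0.005, 0.7), ("ot", 0.011, 0.002, 0.3)],
    )
    api = Component("api", p_api, m=230.0, v=190.0, v_hc=130.0, eps=110.0)
    poly = Component("poly", p_poly, m=25000.0, v=21000.0, v_hc=14500.0, eps=95.0)
    return api, poly


@pytest.fixture
def analytic_pair():
    return gen_analytic_system(2.5)
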
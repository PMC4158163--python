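import numpy as np
import pytest

from abmps import (
    ModelConstants,
    SynthConfig,
    build_default_tree,
    generate_breath,
    load_cohort,
)
from abmps.dsa import Breath


@pytest.fixture(scope="session")
def tree():
    return build_default_tree()


@pytest.fixture(scope="session")
def constants_linear():
    """Gas constants with the minor-loss term switched off."""
    return ModelConstants(k_l=0.0)


@pytest.fixture(scope="session")
def linear_breath():
    """Noiseless breath from a purely linear-resistance tree (alpha=0.57)."""
    cfg = SynthConfig(peep=15.0, alpha_true=0.57, k_l=0.0)
    return cfg, generate_breath(cfg)


@pytest.fixture(scope="session")
def quadratic_breath():
    """Noiseless breath with the minor-loss term at its default value."""
    cfg = SynthConfig(peep=15.0, alpha_true=0.57, k_l=2.0)
    return cfg, generate_breath(cfg)


@pytest.fixture(scope="session")
def cohort():
    return load_cohort()


def make_square_flow_breath(peep=10.0, elastance=20.0, resistance=0.0, n=60, vt=0.5):
    """Analytic breath: square-wave flow (+q0 for 1 s, -q0 for 1 s), triangular
    volume, and P = peep + E*V + R*Q on both limbs.

    With resistance=0 the pressure-volume loop has zero hysteresis.
    """
    t = np.linspace(0.0, 2.0, 2 * n, endpoint=False)
    q0 = vt / 1.0
    q = np.where(t < 1.0, q0, -q0)
    v = np.where(t < 1.0, q0 * t, vt - q0 * (t - 1.0))
    v = np.clip(v, 0.0, None)
    p = peep + elastance * v + resistance * q
    return Breath(time=t, pressure=p, flow=q, volume=v)
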
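import numpy as np
import pytest

from verletdiag.core import CutoffScheme, ScheduleConfig, REDUCED_UNITS
from verletdiag.ljsim import LJPotential, ThermostatConfig, run
from verletdiag.synthetic import gen_lj_fluid


@pytest.fixture(scope="session")
def equilibrated_lj_small():
    """A small equilibrated dense LJ fluid (N=200, rho=0.8, T=1.0, reduced
    units), shared across simulator tests."""
    state = gen_lj_fluid(200, 0.8, 1.0, seed=2)
    pot = LJPotential(1.0, 1.0, 2.5)
    res = run(
        state,
        pot,
        CutoffScheme(r_c=2.5, r_l=2.9),
        ScheduleConfig(dt=0.004, nstlist=10),
        1200,
        thermostat=ThermostatConfig(target=1.0),
        units=REDUCED_UNITS,
    )
    return res.state


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
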
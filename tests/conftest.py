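import numpy as np
import pytest

from semcell import (CellModelParams, NoiseModel, ParticleState, Simulation,
                     derive_pair_params, generate_initial_cell)
from semcell.state import CYTOPLASM, NUCLEUS


@pytest.fixture(scope="session")
def params():
    return CellModelParams()


@pytest.fixture(scope="session")
def pp(params):
    """Derived pair constants at the reference particle count."""
    return derive_pair_params(1000, params)


@pytest.fixture(scope="session")
def pp_small(params):
    return derive_pair_params(100, params)


@pytest.fixture()
def two_particle_state(pp):
    """Two cytoplasmic particles at d_eq along x."""
    pos = np.array([[0.0, 0.0, 0.0], [pp.d_eq, 0.0, 0.0]])
    return ParticleState.from_positions(pos)


@pytest.fixture(scope="session")
def small_cell(pp_small):
    """A relaxed 100-particle cell with nucleus (session-shared, copy before
    mutating)."""
    return generate_initial_cell(100, "sphere", pp_small, seed=7,
                                 with_nucleus=True, R_cell=10.0)


@pytest.fixture(scope="session")
def equilibrated_cell(pp):
    """A 1000-particle cell with nucleus equilibrated with thermal noise for
    2 s (session-shared; used by several mechanics tests)."""
    state = generate_initial_cell(1000, "sphere", pp, seed=3, with_nucleus=True)
    noise = NoiseModel.from_step_fraction(pp, 1e-3, 0.02, seed=3)
    sim = Simulation(state, pp, noise=noise, dt=1e-3)
    sim.run(2000)
    return sim.state
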
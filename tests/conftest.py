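import numpy as np
import pytest

from tisdesign.dynamics import LangevinParams
from tisdesign.systems import (ModelSystem, make_double_well,
                               make_migration_mimic, make_toy_design_space)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def double_well():
    return make_double_well(barrier_height=4.0, well_centers=(-1.0, 1.0),
                            n_env=1, seed=0)


@pytest.fixture(scope="session")
def mimic():
    return make_migration_mimic(n_env=4, gate_strength=3.0, seed=0)


@pytest.fixture(scope="session")
def toy_space():
    return make_toy_design_space(n_sites=3, alphabet_size=4,
                                 effect_table_seed=7)


@pytest.fixture
def params():
    return LangevinParams(dt=1.0, friction=1.0, temperature=300.0, seed=11)


@pytest.fixture(scope="session")
def harmonic_1d():
    """Plain 1D harmonic oscillator without a compiled kernel: exercises the
    generic numpy integrator path."""
    k = 5.0

    def potential(x):
        x = np.asarray(x, dtype=float)
        return 0.5 * k * np.sum(x * x, axis=-1)

    def gradient(x):
        return k * np.asarray(x, dtype=float)

    return ModelSystem(name="h1d", n_coords=1, masses=np.ones(1),
                       potential=potential, gradient=gradient,
                       lambda_spec=("coordinate", 0),
                       metadata={"k": k, "rest_positions": np.zeros(1)})
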
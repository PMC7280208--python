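import numpy as np
import pytest

from aucsas import synthetic
from aucsas.profiles_io import ComponentTable, ScatteringProfile


@pytest.fixture()
def q_grid():
    return np.geomspace(0.010, 0.20, 150)


@pytest.fixture()
def sphere_profile(q_grid):
    """Noise-free sphere curve with Rg = sqrt(3/5)*35.1 ≈ 27.2 Å."""
    i = synthetic.sphere_intensity(35.1, q_grid)
    return ScatteringProfile(q_grid, i, 0.01 * i, concentration=1.0, label="sphere")


@pytest.fixture()
def guinier_profile(q_grid):
    """Exact Guinier curve, Rg = 27.2 Å, I0 = 1."""
    i = np.exp(-(q_grid * 27.2) ** 2 / 3.0)
    return ScatteringProfile(q_grid, i, 0.01 * i, concentration=1.0, label="guinier")


@pytest.fixture()
def bsa_like_table():
    """Monomer 94.1% plus dimer/trimer/tetramer totalling 5.9%."""
    return ComponentTable.from_fractions(synthetic.BSA_LIKE_FRACTIONS)


@pytest.fixture()
def default_mixture():
    spec = synthetic.GeneratorSpec(seed=0)
    i_exp, truth = synthetic.make_mixture(spec)
    table = ComponentTable.from_fractions(spec.fractions)
    return i_exp, truth, table
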
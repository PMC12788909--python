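import numpy as np
import pytest

from atrosim.constitutive import default_material_table
from atrosim.heterogeneity import run_family_experiment
from atrosim.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def table17():
    return default_material_table()


@pytest.fixture(scope="session")
def phantom24():
    """Standard demo-scale phantom: 24^3 grid, 1 mm voxels, 3 mm CSF."""
    return generate_phantom(PhantomSpec(grid_shape=(24, 24, 24), random_seed=7))


@pytest.fixture(scope="session")
def phantom18():
    """Smallest feasible phantom, for cheap solver-level tests."""
    return generate_phantom(PhantomSpec(grid_shape=(18, 18, 18), random_seed=3))


@pytest.fixture(scope="session")
def family_report():
    """Five-variant heterogeneity experiment on one 24^3 phantom.

    20-year horizon in 5-year increments: enough atrophy for clearly
    resolved variant differences at phantom scale.
    """
    spec = PhantomSpec(grid_shape=(24, 24, 24), random_seed=7)
    return run_family_experiment(spec, horizon=20.0, dt=5.0, keep_runs=True)
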
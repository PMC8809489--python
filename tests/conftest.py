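import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from polyscape.crystal_io import UnitCell
from polyscape.synthetic_data import LatticeSpec, generate_crystal, generate_toy_molecule

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_p1():
    """P1, Z=1 toy crystal at θ=118°."""
    return generate_crystal(
        generate_toy_molecule(118.0),
        LatticeSpec(cell=UnitCell(10.0, 10.5, 11.0)),
        seed=1,
        structure_id="toy-p1",
    )


@pytest.fixture(scope="session")
def toy_p21():
    """P2₁, Z=2 toy crystal at θ=118°."""
    return generate_crystal(
        generate_toy_molecule(118.0),
        LatticeSpec(cell=UnitCell(10.0, 11.0, 12.0), spacegroup="P21"),
        seed=2,
        structure_id="toy-p21",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
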
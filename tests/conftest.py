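import numpy as np
import pytest

from knobmap.config import GeneratorConfig
from knobmap.gridgeom import SulcusCurve, build_grid
from knobmap.synthcohort import default_grid


@pytest.fixture(scope="session")
def config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def straight_curve() -> SulcusCurve:
    """A straight 30 mm gyrus-sulcus border along x."""
    n = 31
    return SulcusCurve(np.column_stack([np.linspace(0.0, 30.0, n),
                                        np.zeros(n), np.zeros(n)]))


@pytest.fixture(scope="session")
def straight_grid(straight_curve):
    return build_grid(straight_curve)


@pytest.fixture(scope="session")
def knob_grid():
    """The package's default (gently bowed) hand-knob grid."""
    return default_grid()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
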
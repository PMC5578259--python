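import numpy as np
import pytest

from filmcharge.physchem import BufferSolution, IonSpecies, Medium
from filmcharge.electrokinetics import ColloidSpec


@pytest.fixture
def medium():
    """Water at 298 K with the package's default permittivity/viscosity."""
    return Medium()


@pytest.fixture
def salt_1mM(medium):
    """1 mM NaCl in water at 298 K (Debye length ~9.6 nm)."""
    return BufferSolution(
        pH=7.0,
        ions=(IonSpecies("Na+", +1, 1.0), IonSpecies("Cl-", -1, 1.0)),
        medium=medium,
    )


@pytest.fixture
def anionic_latex():
    """Sulfonate latex sphere: radius 69 nm, bare charge -0.6 e/nm2."""
    return ColloidSpec(radius=69.0, bare_charge_density=-0.6, label="anionic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
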
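import numpy as np
import pytest

from esipred import EnergyModel
from esipred.fixtures import make_charged_shell, make_toy_dimer
from esipred.structure import Atom, Structure


@pytest.fixture(scope="session")
def model():
    return EnergyModel()


@pytest.fixture(scope="session")
def toy_dimer():
    return make_toy_dimer(5, seed=0)


@pytest.fixture(scope="session")
def shell10(model):
    """10-site charged shell with a rugged energy landscape."""
    return make_charged_shell(10, 1.0, gb_values=np.linspace(880, 1000, 10),
                              seed=2)


def simple_structure(positions, elements=None, radii=None):
    """Bare structure from raw nm coordinates (test helper)."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    elements = elements or ["C"] * n
    radii = radii if radii is not None else [0.0] * n
    atoms = [Atom(serial=i + 1, name=elements[i], element=elements[i],
                  residue_name="ALA", residue_index=i + 1, chain_id="A",
                  position=positions[i], radius=radii[i])
             for i in range(n)]
    return Structure(atoms)
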
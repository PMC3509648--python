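import numpy as np
import pytest

from phenoliq.chem import Atom, Molecule
from phenoliq.paper_data import load_fixture


def make_molecule(elements, bonds, coords=None, name="", has_3d=None):
    """Hand-build a Molecule; coordinates default to zeros (graph-only use)."""
    if coords is None:
        coords = [(0.0, 0.0, 0.0)] * len(elements)
        if has_3d is None:
            has_3d = False
    if has_3d is None:
        has_3d = True
    atoms = [Atom(element=el, position=tuple(map(float, xyz))) for el, xyz in zip(elements, coords)]
    return Molecule(atoms=atoms, bonds=[(i, j, 1.0) for i, j in bonds], name=name, has_3d=has_3d)


@pytest.fixture(scope="session")
def fixture_data():
    return load_fixture()


@pytest.fixture(scope="session")
def dataset(fixture_data):
    return fixture_data[0]


@pytest.fixture(scope="session")
def published(fixture_data):
    return fixture_data[1]


@pytest.fixture(scope="session")
def embedded_molecules(dataset):
    """Ten small fixture compounds with 3D coordinates (descriptor oracles)."""
    names = [
        "Gallic acid", "Gentisic acid", "Salicylic acid", "Vanillin", "Tyrosol",
        "4-Hydroxybenzoic acid", "trans-Cinnamic acid", "DOPAC",
        "3-Methoxybenzoic acid", "p-Coumaric acid",
    ]
    return [dataset.molecule(name, embed=True, seed=7) for name in names]


@pytest.fixture
def water():
    """Bent water geometry (O-H 0.9572 A, H-O-H 104.5 degrees)."""
    import math

    angle = math.radians(104.5)
    r = 0.9572
    coords = [
        (0.0, 0.0, 0.0),
        (r, 0.0, 0.0),
        (r * math.cos(angle), r * math.sin(angle), 0.0),
    ]
    atoms = [Atom("O", coords[0]), Atom("H", coords[1]), Atom("H", coords[2])]
    return Molecule(atoms=atoms, bonds=[(0, 1, 1.0), (0, 2, 1.0)], name="water")
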
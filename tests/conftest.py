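import numpy as np
import pytest

from craft.model_io import (AtomRecord, Chain, Residue, SpaceGroup,
                            StructureModel, UnitCell)
from craft.synthetic import make_helix_model


@pytest.fixture
def ortho_cell():
    return UnitCell(20.0, 30.0, 40.0)


@pytest.fixture
def cube_cell():
    return UnitCell(20.0, 20.0, 20.0)


@pytest.fixture
def helix_cell():
    return UnitCell(20.0, 20.0, 30.0)


@pytest.fixture
def helix(helix_cell):
    return make_helix_model(10, helix_cell, "P 1", seed=0)


@pytest.fixture
def helix_p21(helix_cell):
    return make_helix_model(10, helix_cell, "P 21", seed=0)


def single_atom_model(cell, pos, element="O", spacegroup="P 1", name="O"):
    res = Residue("A", 1, "HOH", "", [AtomRecord(name, element, np.asarray(pos, float))])
    return StructureModel(cell, SpaceGroup.from_symbol(spacegroup),
                          [Chain("A", [res])])


def atoms_model(cell, positions, element="O", spacegroup="P 1"):
    ch = Chain("A")
    for i, p in enumerate(positions):
        ch.residues.append(
            Residue("A", i + 1, "HOH", "",
                    [AtomRecord("O", element, np.asarray(p, float))]))
    return StructureModel(cell, SpaceGroup.from_symbol(spacegroup), [ch])
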
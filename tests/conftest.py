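import numpy as np
import pytest

from patchscreen.structure import AtomRecord, ResidueRecord, StructureModel


def bead_model(positions, amino_acids, radius=3.0, chain_id="A"):
    """One pseudo-atom per residue at the given coordinates."""
    atoms, residues = [], []
    for i, (pos, aa) in enumerate(zip(positions, amino_acids)):
        residues.append(ResidueRecord(chain_id, str(i + 1), aa))
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name="CA",
                element="C",
                residue_index=i,
                coordinates=tuple(float(x) for x in pos),
                vdw_radius=radius,
            )
        )
    return StructureModel(atoms=atoms, residues=residues)


@pytest.fixture
def single_atom_model():
    return bead_model([(0.0, 0.0, 0.0)], ["G"], radius=1.7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
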
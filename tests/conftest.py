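import numpy as np
import pytest

from ssbkit.structure_io import Atom, StructureModel
from ssbkit.synthetic_data import ToyTetramerSpec, build_toy_tetramer


@pytest.fixture
def toy_tetramer() -> StructureModel:
    """4-chain D2 Cα toy tetramer with charged residues on every chain."""
    return build_toy_tetramer(ToyTetramerSpec(monomer_sequence="AEKARDGLSTVE"))


@pytest.fixture
def toy_tetramer_sidechain() -> StructureModel:
    return build_toy_tetramer(
        ToyTetramerSpec(monomer_sequence="AEKARDGLSTVE", representation="minimal_sidechain")
    )


def make_ca_model(coords, chains=None, resnames=None) -> StructureModel:
    """One-CA-per-residue model from an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    chains = chains or ["A"] * n
    resnames = resnames or ["GLY"] * n
    atoms = [
        Atom(i + 1, "CA", "C", resnames[i], i + 1, chains[i], coords[i])
        for i in range(n)
    ]
    return StructureModel(atoms)
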
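import numpy as np
import pytest

from protex.io import parse_pdb
from protex.synthetic import ChainRecipe, synthetic_ligand, synthetic_protein


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def helix_structure():
    text, _ = synthetic_protein(ChainRecipe(n_residues=40, geometry="helix", seed=7), "helix40")
    return parse_pdb(text, "protein", "helix40")


@pytest.fixture(scope="session")
def walk_structure():
    text, _ = synthetic_protein(
        ChainRecipe(n_residues=40, geometry="random_walk", seed=8), "walk40"
    )
    return parse_pdb(text, "protein", "walk40")


@pytest.fixture(scope="session")
def ligand_structure():
    return parse_pdb(synthetic_ligand(10, seed=9, structure_id="lig10"), "ligand", "lig10")
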
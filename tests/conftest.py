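import numpy as np
import pytest
from hypothesis import settings
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from moldesirer.fixtures import build_toy_fragment_table, build_toy_receptor, full_fragment_table
from moldesirer.mutation import Fragment, FragmentTable

RDLogger.DisableLog("rdApp.warning")


@pytest.fixture(scope="session")
def toy_table() -> FragmentTable:
    return build_toy_fragment_table(seed=0, n_fragments=12, max_heavy=6)


@pytest.fixture(scope="session")
def grow_table() -> FragmentTable:
    """Minimal grow table: methyl and ethyl only."""
    return FragmentTable([Fragment("[*]C", 1), Fragment("[*]CC", 2)])


@pytest.fixture(scope="session")
def full_table() -> FragmentTable:
    return full_fragment_table()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toluene_3d() -> Chem.Mol:
    """Toluene with one optimized 3D conformer (constrained-embed reference)."""
    mol = Chem.AddHs(Chem.MolFromSmiles("Cc1ccccc1"))
    AllChem.EmbedMolecule(mol, randomSeed=42)
    AllChem.MMFFOptimizeMolecule(mol)
    return Chem.RemoveHs(mol)


@pytest.fixture(scope="session")
def wall_pdb(tmp_path_factory) -> str:
    path = tmp_path_factory.mktemp("receptors") / "wall.pdb"
    path.write_text(build_toy_receptor("wall"))
    return str(path)


@pytest.fixture(scope="session")
def cavity_pdb(tmp_path_factory) -> str:
    path = tmp_path_factory.mktemp("receptors") / "cavity.pdb"
    path.write_text(build_toy_receptor("cavity"))
    return str(path)
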
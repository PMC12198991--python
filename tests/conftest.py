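import pytest

from thermogav import packaged
from thermogav.group_perception import from_smiles

DITA_34_SMILES = (
    "OC(=O)c1ccc(N2C(=O)c3ccc(C(=O)O)cc3C2=O)"
    "c(N2C(=O)c3ccc(C(=O)O)cc3C2=O)c1"
)
DITA_35_SMILES = (
    "OC(=O)c1cc(N2C(=O)c3ccc(C(=O)O)cc3C2=O)"
    "cc(N2C(=O)c3ccc(C(=O)O)cc3C2=O)c1"
)


@pytest.fixture(scope="session")
def gav_table():
    return packaged.gav_table()


@pytest.fixture(scope="session")
def species():
    return packaged.species_table()


@pytest.fixture(scope="session")
def study():
    return packaged.study_inputs()


@pytest.fixture(scope="session")
def dita_mols():
    return {
        "3,4-DITA": from_smiles(DITA_34_SMILES),
        "3,5-DITA": from_smiles(DITA_35_SMILES),
    }
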
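import sys
from pathlib import Path

import pytest
from rdkit import Chem, RDLogger

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

RDLogger.DisableLog("rdApp.*")

#: diverse small molecules (all <= 12 heavy atoms) for descriptor-oracle
#: comparisons: alkanes, branched alkanes, rings, heteroaromatics,
#: common functional groups, fused systems, nitrogen-rich structures.
SMALL_MOLECULES = [
    "C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC", "CCCCCCC", "CCCCCCCC",
    "CC(C)C", "CC(C)CC", "CC(C)(C)C", "CCC(C)CC", "CC(C)C(C)C", "CC(C)(C)CC",
    "CCC(CC)CC", "CC(C)(C)C(C)C",
    "C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1", "C1CCCCCC1",
    "CC1CCCCC1", "CC1CCC(C)CC1", "C1CCC2CCCCC2C1", "C1CCC2(CC1)CCCC2",
    "c1ccccc1", "Cc1ccccc1", "Cc1ccc(C)cc1", "c1ccc2ccccc2c1",
    "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cscn1", "c1cnc2[nH]ccc2c1",
    "c1cnco1", "c1cnn[nH]1", "c1ccc(O)cc1", "Clc1ccccc1", "Fc1ccc(F)cc1",
    "CCO", "CC(C)O", "CC(=O)O", "CC(=O)OC", "CC(=O)N", "CC#N", "CCN",
    "CCNCC", "CN(C)C", "CN(C)CCN", "NCCCN(C)C", "NCCN", "CNC",
    "OCC(O)CO", "OC1CCCCC1", "O=C1CCCCC1", "CC(=O)c1ccccc1",
    "Cc1ccccc1[N+](=O)[O-]", "NC(=O)c1ccccc1", "CSC", "CCSSCC",
    "OC(=O)c1ccccc1", "CC(C)(C)c1ccccc1", "C1CCC(CC1)N", "CC(N)C(=O)O",
]


@pytest.fixture(scope="session")
def small_mols():
    mols = [(smi, Chem.MolFromSmiles(smi)) for smi in SMALL_MOLECULES]
    assert all(m is not None for _, m in mols)
    assert all(m.GetNumHeavyAtoms() <= 12 for _, m in mols)
    return mols


@pytest.fixture(scope="session")
def feature_library():
    from screenmine.scaffolds import FeatureLibrary

    return FeatureLibrary.load()
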
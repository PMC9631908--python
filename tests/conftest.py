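import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from matqsar.chem_core import parse_smiles
from matqsar.curation import ActivityDataset


@pytest.fixture(scope="session")
def mol():
    """Factory: cached SMILES → Molecule."""
    cache = {}

    def factory(smiles):
        if smiles not in cache:
            cache[smiles] = parse_smiles(smiles)
        return cache[smiles]

    return factory


#: Small fixture molecules (≤ 12 heavy atoms) spanning the relevant
#: functional groups; used for oracle comparisons and property tests.
FIXTURE_SMILES = [
    "C", "CC", "CCC", "CCCCC", "CCCCCC", "CCCCCCCCCC",
    "C1CCCCC1", "CC1CCCCC1", "c1ccccc1", "Cc1ccccc1",
    "CCO", "CC(=O)O", "NCC(=O)O", "c1ccccc1O", "CCN", "CNC",
    "NCCc1ccccc1", "CNC(C)Cc1ccccc1", "CC(N)Cc1ccccc1",
    "CNC(C)C(=O)c1ccccc1", "NC1Cc2ccccc2C1", "CCOC(=O)C", "CC(=O)NC",
]


@pytest.fixture(scope="session")
def fixture_mols(mol):
    return {s: mol(s) for s in FIXTURE_SMILES}


def make_dataset(entries, target="dat"):
    """Build an ActivityDataset from (id, smiles, pki) triples."""
    ids = [e[0] for e in entries]
    frame = pd.DataFrame(
        {
            "smiles": [e[1] for e in entries],
            f"pki_{target}": [e[2] for e in entries],
        },
        index=pd.Index(ids, name="compound_id"),
    )
    molecules = {e[0]: parse_smiles(e[1]) for e in entries}
    return ActivityDataset(table=frame, molecules=molecules)


@pytest.fixture
def toy_dataset():
    """Ten NPS-like compounds with hand-assigned DAT pKi values."""
    return make_dataset(
        [
            ("amp", "NC(C)Cc1ccccc1", 6.2),
            ("meth", "CNC(C)Cc1ccccc1", 6.8),
            ("mdma", "CNC(C)Cc1ccc2c(c1)OCO2", 5.9),
            ("cath", "NC(C)C(=O)c1ccccc1", 5.2),
            ("meph", "CNC(C)C(=O)c1ccc(C)cc1", 5.6),
            ("ai", "NC1Cc2ccccc2C1", 4.7),
            ("mai", "CNC1Cc2ccccc2C1", 4.4),
            ("pvp", "CCCC(N1CCCC1)C(=O)c1ccccc1", 7.3),
            ("pe", "NCCc1ccccc1", 4.1),
            ("tyra", "NCCc1ccc(O)cc1", 6.5),
        ]
    )
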
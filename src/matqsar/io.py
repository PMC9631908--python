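"""CSV readers/writers for the standard pipeline file formats.

Three plain-text schemas travel between stages:

* compound CSV — ``compound_id, smiles, pki_dat, pki_net, pki_sert``
  (activity columns optional per target, missing values allowed);
* descriptor CSV — ``compound_id`` plus one column per descriptor;
* score CSV — ``ligand_id`` plus one column per scoring function, with
  orientations supplied separately (config).
"""

from __future__ import annotations

import pandas as pd

from .chem_core import parse_smiles
from .consensus import ScoreTable
from .curation import ActivityDataset

__all__ = [
    "read_compound_csv",
    "write_compound_csv",
    "read_score_csv",
    "write_score_csv",
]


def read_compound_csv(path) -> ActivityDataset:
    """Load a compound table and parse every SMILES."""
    df = pd.read_csv(path, dtype={"compound_id": str})
    required = {"compound_id", "smiles"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"compound CSV missing columns: {sorted(missing)}")
    df = df.set_index("compound_id")
    molecules = {}
    for cid, smiles in df["smiles"].items():
        molecules[cid] = parse_smiles(smiles)
    return ActivityDataset(table=df, molecules=molecules)


def write_compound_csv(d: ActivityDataset, path) -> None:
    d.table.to_csv(path, float_format="%.12g")


def read_score_csv(path, higher_better: dict[str, bool]) -> ScoreTable:
    """Load a ligand × scoring-function table with declared orientations."""
    df = pd.read_csv(path, dtype={"ligand_id": str})
    if "ligand_id" not in df.columns:
        raise ValueError("score CSV missing 'ligand_id' column")
    df = df.set_index("ligand_id")
    return ScoreTable(scores=df, higher_better=dict(higher_better))


def write_score_csv(t: ScoreTable, path) -> None:
    t.scores.to_csv(path, float_format="%.12g")
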
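"""The eight model descriptors, table assembly and max-scaling.

The descriptors are the ones that appear in the final transporter
models: a chain-length/rigidity term (``b_max1len``), hydrophobic-surface
terms (``fasa_h``, ``peoe_vsa_neg0``, ``peoe_vsa_pos3``, ``q_vsa_fpneg``),
a lead-likeness indicator (``opr_leadlike``), a hydrogen-bond-donor count
(``a_don``) and a torsional strain energy (``e_tor``). Charge-binned
surface descriptors combine the PEOE charges and the analytic vdW surface
from :mod:`matqsar.chem_core`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors as RDDescriptors, rdMolDescriptors

from .chem_core import Molecule, atom_vdw_surface, compute_peoe_charges

__all__ = [
    "DESCRIPTOR_NAMES",
    "PEOE_BIN_EDGES",
    "DescriptorTable",
    "DescriptorError",
    "b_max1len",
    "fasa_h",
    "opr_leadlike",
    "oprea_violations",
    "peoe_vsa_bin",
    "peoe_vsa_neg0",
    "peoe_vsa_pos3",
    "q_vsa_fpneg",
    "a_don",
    "e_tor",
    "compute_descriptor",
    "build_table",
    "scale_table",
    "unscale_table",
    "apply_scaling",
    "read_table_csv",
    "write_table_csv",
]

#: Canonical descriptor order used throughout the pipeline.
DESCRIPTOR_NAMES = (
    "b_max1len",
    "fasa_h",
    "opr_leadlike",
    "peoe_vsa_neg0",
    "peoe_vsa_pos3",
    "q_vsa_fpneg",
    "a_don",
    "e_tor",
)

#: Standard 14-bin charge partition for PEOE/VSA descriptors.
PEOE_BIN_EDGES = (
    -np.inf, -0.30, -0.25, -0.20, -0.15, -0.10, -0.05,
    0.00, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, np.inf,
)

HYDROPHOBIC_ABS_CHARGE = 0.2  # |q| below this counts as hydrophobic (FASA_H)
POLAR_NEG_CHARGE = -0.2       # q below this counts as negative polar (Q_VSA_FPNEG)


class DescriptorError(ValueError):
    """A descriptor could not be computed for one or more molecules."""


@dataclass(frozen=True)
class DescriptorTable:
    """Molecules × named descriptors, with explicit scaling state.

    ``values`` is indexed by compound id with one column per descriptor.
    After :func:`scale_table`, each non-constant column has max|value| = 1
    and the original per-column maxima are kept in ``scaling_maxima`` so
    that scaling can be applied to new rows or inverted exactly.
    """

    values: pd.DataFrame
    scaled: bool = False
    scaling_maxima: pd.Series | None = None

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)


def _acyclic_single_bond_graph(rdmol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(a.GetIdx() for a in rdmol.GetAtoms())
    for bond in rdmol.GetBonds():
        if (
            bond.GetBondType() == Chem.BondType.SINGLE
            and not bond.GetIsAromatic()
            and not bond.IsInRing()
        ):
            g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    return g


def b_max1len(mol: Molecule) -> int:
    """Number of bonds in the longest chain of acyclic single bonds.

    Ring bonds and multiple/aromatic bonds are excluded, so the retained
    subgraph is a forest and the answer is the largest tree diameter
    (double-BFS). Returns 0 for molecules with no acyclic single bond.
    """
    g = _acyclic_single_bond_graph(mol.rdmol)
    best = 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        start = next(iter(comp))
        far = max(nx.single_source_shortest_path_length(sub, start).items(), key=lambda kv: kv[1])[0]
        diameter = max(nx.single_source_shortest_path_length(sub, far).values())
        best = max(best, diameter)
    return best


def fasa_h(mol: Molecule) -> float:
    """Fraction of the vdW surface on hydrophobic atoms (|q| < 0.2)."""
    q = compute_peoe_charges(mol).charges
    s = atom_vdw_surface(mol)
    if s.total <= 0:
        raise DescriptorError(f"zero surface area for {mol.canonical_smiles}")
    return float(np.sum(s.areas[np.abs(q) < HYDROPHOBIC_ABS_CHARGE]) / s.total)


#: Oprea lead-likeness rules as (label, predicate-on-rdmol) pairs.
_OPREA_RULES = (
    ("mw_le_450", lambda m: RDDescriptors.MolWt(m) <= 450.0),
    ("logp_in_-3.5_4.5", lambda m: -3.5 <= Crippen.MolLogP(m) <= 4.5),
    ("rings_le_4", lambda m: rdMolDescriptors.CalcNumRings(m) <= 4),
    ("rot_bonds_le_10", lambda m: rdMolDescriptors.CalcNumRotatableBonds(m) <= 10),
    ("hbd_le_5", lambda m: rdMolDescriptors.CalcNumHBD(m) <= 5),
    ("hba_le_8", lambda m: rdMolDescriptors.CalcNumHBA(m) <= 8),
)


def oprea_violations(mol: Molecule) -> list[str]:
    """Labels of the Oprea lead-likeness rules the molecule violates."""
    return [label for label, ok in _OPREA_RULES if not ok(mol.rdmol)]


def opr_leadlike(mol: Molecule) -> int:
    """1 if the molecule violates at most two lead-like criteria, else 0."""
    return 1 if len(oprea_violations(mol)) <= 2 else 0


def peoe_vsa_bin(mol: Molecule, lo: float, hi: float) -> float:
    """vdW surface area (Å²) on atoms with PEOE charge in [lo, hi)."""
    if lo >= hi:
        raise ValueError(f"empty charge bin: lo={lo} >= hi={hi}")
    q = compute_peoe_charges(mol).charges
    s = atom_vdw_surface(mol)
    return float(np.sum(s.areas[(q >= lo) & (q < hi)]))


def peoe_vsa_neg0(mol: Molecule) -> float:
    """Surface area with partial charge in [−0.05, 0) — PEOE_VSA−0."""
    return peoe_vsa_bin(mol, -0.05, 0.0)


def peoe_vsa_pos3(mol: Molecule) -> float:
    """Surface area with partial charge in [0.15, 0.20) — PEOE_VSA+3."""
    return peoe_vsa_bin(mol, 0.15, 0.20)


def q_vsa_fpneg(mol: Molecule) -> float:
    """Fractional negative polar surface area (charge < −0.2)."""
    q = compute_peoe_charges(mol).charges
    s = atom_vdw_surface(mol)
    if s.total <= 0:
        raise DescriptorError(f"zero surface area for {mol.canonical_smiles}")
    return float(np.sum(s.areas[q < POLAR_NEG_CHARGE]) / s.total)


# Basic aliphatic amine: neutral sp3 N not adjacent to a carbonyl-like
# group or an aromatic system. Such nitrogens are protonated at
# physiological pH and are excluded from the donor count.
_BASIC_AMINE = Chem.MolFromSmarts(
    "[NX3;+0;!$([N]-[C,S,P]=[O,S,N]);!$([N]-a);!$([N]=*)]"
)


def a_don(mol: Molecule) -> int:
    """Hydrogen-bond-donor atoms, excluding basic (or protonated) amines.

    Counts O–H and N–H bearing atoms; amphiprotic groups (hydroxyl,
    phenol, amide N–H) count, while basic aliphatic amines and cationic
    nitrogens do not.
    """
    rdmol = mol.rdmol
    basic = {m[0] for m in rdmol.GetSubstructMatches(_BASIC_AMINE)}
    count = 0
    for atom in rdmol.GetAtoms():
        z = atom.GetAtomicNum()
        if z not in (7, 8) or atom.GetTotalNumHs() == 0:
            continue
        if z == 7 and (atom.GetIdx() in basic or atom.GetFormalCharge() > 0):
            continue
        count += 1
    return count


def _embed_3d(mol: Molecule, seed: int) -> Chem.Mol:
    molh = Chem.AddHs(mol.rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    if AllChem.EmbedMolecule(molh, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(molh, params) != 0:
            raise DescriptorError(f"3D embedding failed for {mol.canonical_smiles}")
    return molh

# Rotation barriers (kcal/mol) for the shifted threefold torsion term.
_TORSION_BARRIER_SP3 = 2.9   # ethane-like
_TORSION_BARRIER_OTHER = 2.0


def e_tor(mol: Molecule, seed: int = 2024) -> float:
    """Torsional potential energy (kcal/mol) on a deterministic conformer.

    A distance-geometry conformer is generated from ``seed`` and every
    proper torsion about an acyclic single bond contributes a shifted
    threefold cosine term ``V/2·(1 + cos 3φ)`` (≥ 0 by construction),
    normalised by the number of torsions sharing the central bond. The
    barrier V is 2.9 kcal/mol for sp3–sp3 central bonds and 2.0 otherwise.
    """
    if mol.rdmol.GetNumHeavyAtoms() < 2:
        return 0.0
    molh = _embed_3d(mol, seed)
    conf = molh.GetConformer()
    total = 0.0
    for bond in molh.GetBonds():
        if (
            bond.GetBondType() != Chem.BondType.SINGLE
            or bond.GetIsAromatic()
            or bond.IsInRing()
        ):
            continue
        j_at, k_at = bond.GetBeginAtom(), bond.GetEndAtom()
        i_nbrs = [a for a in j_at.GetNeighbors() if a.GetIdx() != k_at.GetIdx()]
        l_nbrs = [a for a in k_at.GetNeighbors() if a.GetIdx() != j_at.GetIdx()]
        if not i_nbrs or not l_nbrs:
            continue
        sp3 = (
            j_at.GetHybridization() == Chem.HybridizationType.SP3
            and k_at.GetHybridization() == Chem.HybridizationType.SP3
        )
        barrier = _TORSION_BARRIER_SP3 if sp3 else _TORSION_BARRIER_OTHER
        m = len(i_nbrs) * len(l_nbrs)
        for i_at, l_at in itertools.product(i_nbrs, l_nbrs):
            phi = AllChem.GetDihedralRad(
                conf, i_at.GetIdx(), j_at.GetIdx(), k_at.GetIdx(), l_at.GetIdx()
            )
            total += (barrier / (2.0 * m)) * (1.0 + np.cos(3.0 * phi))
    return float(max(total, 0.0))


_DESCRIPTOR_FUNCS = {
    "b_max1len": lambda mol, seed: float(b_max1len(mol)),
    "fasa_h": lambda mol, seed: fasa_h(mol),
    "opr_leadlike": lambda mol, seed: float(opr_leadlike(mol)),
    "peoe_vsa_neg0": lambda mol, seed: peoe_vsa_neg0(mol),
    "peoe_vsa_pos3": lambda mol, seed: peoe_vsa_pos3(mol),
    "q_vsa_fpneg": lambda mol, seed: q_vsa_fpneg(mol),
    "a_don": lambda mol, seed: float(a_don(mol)),
    "e_tor": lambda mol, seed: e_tor(mol, seed),
}


def compute_descriptor(mol: Molecule, name: str, seed: int = 2024) -> float:
    """Compute a single named descriptor."""
    try:
        func = _DESCRIPTOR_FUNCS[name]
    except KeyError:
        raise DescriptorError(
            f"unknown descriptor {name!r}; available: {', '.join(DESCRIPTOR_NAMES)}"
        ) from None
    return func(mol, seed)


def build_table(
    mols: list[Molecule],
    names: tuple[str, ...] | list[str] = DESCRIPTOR_NAMES,
    ids: list[str] | None = None,
    seed: int = 2024,
) -> DescriptorTable:
    """Assemble the unscaled molecules × descriptors matrix.

    Row order follows the input; errors for individual molecules are
    aggregated into a single :class:`DescriptorError`.
    """
    if ids is None:
        ids = [m.canonical_smiles for m in mols]
    if len(ids) != len(mols):
        raise ValueError("ids and mols must have equal length")
    rows, failures = [], []
    for cid, mol in zip(ids, mols):
        try:
            rows.append({name: compute_descriptor(mol, name, seed) for name in names})
        except (DescriptorError, ValueError) as exc:
            failures.append(f"{cid}: {exc}")
    if failures:
        raise DescriptorError("descriptor computation failed for:\n" + "\n".join(failures))
    df = pd.DataFrame(rows, index=pd.Index(ids, name="compound_id"), columns=list(names))
    return DescriptorTable(values=df, scaled=False)


def scale_table(t: DescriptorTable) -> DescriptorTable:
    """Divide each column by its maximum absolute value.

    Constant-zero columns are left at 0 (their stored maximum is 0, which
    flags them as carrying no signal). Raises if the table is already
    scaled.
    """
    if t.scaled:
        raise ValueError("table is already scaled")
    maxima = t.values.abs().max(axis=0)
    safe = maxima.replace(0.0, 1.0)
    return DescriptorTable(values=t.values / safe, scaled=True, scaling_maxima=maxima)


def unscale_table(t: DescriptorTable) -> DescriptorTable:
    """Invert :func:`scale_table` exactly using the stored maxima."""
    if not t.scaled or t.scaling_maxima is None:
        raise ValueError("table is not scaled")
    safe = t.scaling_maxima.replace(0.0, 1.0)
    return DescriptorTable(values=t.values * safe, scaled=False)


def apply_scaling(t: DescriptorTable, maxima: pd.Series) -> DescriptorTable:
    """Scale an unscaled table with externally supplied column maxima.

    Used to place test-set rows on the training set's scale.
    """
    if t.scaled:
        raise ValueError("table is already scaled")
    missing = [c for c in t.values.columns if c not in maxima.index]
    if missing:
        raise ValueError(f"no scaling maxima for columns: {missing}")
    safe = maxima.reindex(t.values.columns).replace(0.0, 1.0)
    return DescriptorTable(values=t.values / safe, scaled=True, scaling_maxima=maxima)


def write_table_csv(t: DescriptorTable, path) -> None:
    t.values.to_csv(path, float_format="%.12g")


def read_table_csv(path, scaled: bool = False) -> DescriptorTable:
    df = pd.read_csv(path, index_col="compound_id")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"missing descriptor values for: {bad}")
    return DescriptorTable(values=df, scaled=scaled)
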
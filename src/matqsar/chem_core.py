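"""Chemical-graph primitives: parsing, charges, surfaces, fingerprints.

Everything downstream (descriptors, similarity-based curation) is built on
four per-molecule quantities computed here:

* PEOE (Gasteiger–Marsili) partial charges, hydrogens summed onto their
  heavy atoms;
* an analytic, conformation-free approximation of the per-atom van der
  Waals surface area (pairwise sphere-overlap correction over bonded
  pairs at ideal bond lengths);
* hashed linear-path fingerprints and their Tanimoto similarity;
* a small rule-based protonation model for physiological pH.

RDKit supplies the molecular graph, aromaticity perception and the
Gasteiger charge iteration; the surface model and the protonation rules
are implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule",
    "AtomCharges",
    "AtomSurface",
    "Fingerprint",
    "ParseError",
    "UnsupportedElementError",
    "parse_smiles",
    "assign_ph_protonation",
    "compute_peoe_charges",
    "atom_vdw_surface",
    "fingerprint",
    "tanimoto",
]


class ParseError(ValueError):
    """SMILES string could not be parsed into a valid molecule."""


class UnsupportedElementError(ValueError):
    """Molecule contains an element without charge/radius parameters."""


@dataclass(frozen=True)
class Molecule:
    """A valence-checked molecular graph.

    Wraps an RDKit ``Mol`` (implicit hydrogens, aromaticity perceived,
    largest covalent fragment only) together with its canonical SMILES,
    which serves as the molecule's identity for caching and equality.
    ``protonated_at`` records the pH used by :func:`assign_ph_protonation`,
    or ``None`` for the as-parsed ionisation state.
    """

    rdmol: Chem.Mol
    canonical_smiles: str
    protonated_at: float | None = None

    @property
    def num_heavy_atoms(self) -> int:
        return self.rdmol.GetNumHeavyAtoms()

    @property
    def total_formal_charge(self) -> int:
        return Chem.GetFormalCharge(self.rdmol)

    def __eq__(self, other) -> bool:  # identity by canonical SMILES
        return isinstance(other, Molecule) and self.canonical_smiles == other.canonical_smiles

    def __hash__(self) -> int:
        return hash(self.canonical_smiles)


@dataclass(frozen=True)
class AtomCharges:
    """Per-heavy-atom PEOE partial charges (e), hydrogens summed in."""

    charges: np.ndarray
    n_iterations: int

    @property
    def total(self) -> float:
        return float(np.sum(self.charges))


@dataclass(frozen=True)
class AtomSurface:
    """Per-heavy-atom approximate vdW surface areas (Å²), hydrogens summed in."""

    areas: np.ndarray

    @property
    def total(self) -> float:
        return float(np.sum(self.areas))


@dataclass(frozen=True)
class Fingerprint:
    """Hashed linear-path bit vector with its generation parameters."""

    bits: frozenset[int]
    n_bits: int = 1024
    max_path: int = 7

    @property
    def popcount(self) -> int:
        return len(self.bits)

    def compatible_with(self, other: "Fingerprint") -> bool:
        return self.n_bits == other.n_bits and self.max_path == other.max_path


def parse_smiles(text: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Salts/mixtures are reduced to the largest covalent fragment (by heavy
    atom count, ties broken by canonical SMILES for determinism).

    Raises
    ------
    ParseError
        If the string is empty, syntactically invalid, or violates
        valence rules.
    """
    if not isinstance(text, str) or not text.strip():
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(text.strip(), sanitize=True)
    if mol is None:
        raise ParseError(f"could not parse SMILES {text!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: (m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))
    return Molecule(rdmol=mol, canonical_smiles=Chem.MolToSmiles(mol))


# Minimal pKa rule table: (label, SMARTS, pKa, kind). "base" groups gain a
# proton when pH < pKa; "acid" groups lose one when pH > pKa. The first
# matched atom of each SMARTS is the site that is (de)protonated.
_PKA_RULES: tuple[tuple[str, str, float, str], ...] = (
    # amidines/guanidines before plain amines so the =N site wins
    ("amidine", "[NX2;+0]=[CX3]([#6,#7])[NX3;+0]", 12.4, "base"),
    # aliphatic amine: sp3 N, neutral, not amide/sulfonamide, not aromatic,
    # not bonded to an aromatic ring (anilines are weak bases, pKa ~4.6)
    (
        "aliphatic_amine",
        "[NX3;+0;!$([N]-[C,S,P]=[O,S,N]);!$([N]-a);!$([N]=*)]",
        10.0,
        "base",
    ),
    ("carboxylic_acid", "[CX3](=O)[OX2H1]", 4.8, "acid"),
    ("phenol", "[c][OX2H1]", 10.0, "acid"),
)


def assign_ph_protonation(mol: Molecule, ph: float = 7.0) -> Molecule:
    """Assign ionisation states at the given pH by a minimal pKa rule set.

    Aliphatic amines and amidines are protonated (+1) and carboxylic acids
    deprotonated (−1) at pH 7; phenols stay neutral. Molecules without a
    matching group are returned with unchanged charges.
    """
    rw = Chem.RWMol(mol.rdmol)
    handled: set[int] = set()
    for _label, smarts, pka, kind in _PKA_RULES:
        patt = Chem.MolFromSmarts(smarts)
        for match in rw.GetSubstructMatches(patt):
            # bases protonate the first SMARTS atom, acids deprotonate the last (the O-H)
            idx = match[0] if kind == "base" else match[-1]
            if idx in handled:
                continue
            atom = rw.GetAtomWithIdx(idx)
            if kind == "base" and ph < pka and atom.GetFormalCharge() == 0:
                atom.SetFormalCharge(+1)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
                atom.SetNoImplicit(True)
                handled.add(idx)
            elif kind == "acid" and ph > pka and atom.GetFormalCharge() == 0 and atom.GetTotalNumHs() >= 1:
                atom.SetFormalCharge(-1)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() - 1)
                atom.SetNoImplicit(True)
                handled.add(idx)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Molecule(rdmol=out, canonical_smiles=Chem.MolToSmiles(out), protonated_at=ph)


def _heavy_atom_hydrogen_map(molh: Chem.Mol) -> tuple[list[int], dict[int, int]]:
    """Indices of heavy atoms and a map hydrogen-index -> heavy parent."""
    heavy = [a.GetIdx() for a in molh.GetAtoms() if a.GetAtomicNum() != 1]
    hmap: dict[int, int] = {}
    for atom in molh.GetAtoms():
        if atom.GetAtomicNum() == 1:
            nbrs = atom.GetNeighbors()
            if nbrs:
                hmap[atom.GetIdx()] = nbrs[0].GetIdx()
    return heavy, hmap


def compute_peoe_charges(
    mol: Molecule, n_iter: int = 6, sum_hydrogens: bool = True
) -> AtomCharges:
    """Gasteiger–Marsili PEOE partial charges, damping halved per iteration.

    Hydrogens are made explicit for the iteration; with ``sum_hydrogens``
    (the descriptor-package convention used for charge binning) their
    charges are folded onto the attached heavy atom, so the returned
    vector has one entry per heavy atom in graph order.

    Raises
    ------
    UnsupportedElementError
        If any element lacks electronegativity parameters.
    """
    molh = Chem.AddHs(mol.rdmol)
    AllChem.ComputeGasteigerCharges(molh, nIter=n_iter, throwOnParamFailure=False)
    raw = np.array([float(a.GetProp("_GasteigerCharge")) for a in molh.GetAtoms()])
    if not np.all(np.isfinite(raw)):
        bad = sorted(
            {molh.GetAtomWithIdx(i).GetSymbol() for i in np.nonzero(~np.isfinite(raw))[0]}
        )
        raise UnsupportedElementError(f"no PEOE parameters for element(s): {', '.join(bad)}")
    heavy, hmap = _heavy_atom_hydrogen_map(molh)
    summed = {i: raw[i] for i in heavy}
    if sum_hydrogens:
        for h_idx, parent in hmap.items():
            summed[parent] += raw[h_idx]
    charges = np.array([summed[i] for i in heavy])
    return AtomCharges(charges=charges, n_iterations=n_iter)


# Bond-order-dependent contraction of the ideal bond length (sum of
# covalent radii); aromatic bonds sit between single and double.
_BOND_ORDER_SCALE = {1.0: 1.0, 1.5: 0.92, 2.0: 0.87, 3.0: 0.78}


def _sphere_cap_hidden(ri: float, rj: float, d: float) -> float:
    """Area of sphere i buried inside sphere j at centre distance d."""
    if d >= ri + rj:
        return 0.0
    if d + ri <= rj:
        return 4.0 * math.pi * ri * ri
    if d + rj <= ri:
        return 0.0
    h = ri - (d * d + ri * ri - rj * rj) / (2.0 * d)
    return 2.0 * math.pi * ri * max(h, 0.0)


def atom_vdw_surface(mol: Molecule) -> AtomSurface:
    """Approximate per-atom accessible van der Waals surface area (Å²).

    Conformation-free: each atom is a vdW sphere and the area buried in
    each *bonded* neighbour's sphere (spherical-cap geometry at the ideal
    bond length, i.e. the sum of covalent radii scaled by bond order) is
    subtracted. Hydrogen areas are summed onto their heavy atom.

    Raises
    ------
    UnsupportedElementError
        If any element lacks a vdW or covalent radius.
    """
    pt = Chem.GetPeriodicTable()
    molh = Chem.AddHs(mol.rdmol)
    n = molh.GetNumAtoms()
    radii = np.empty(n)
    for atom in molh.GetAtoms():
        z = atom.GetAtomicNum()
        r = pt.GetRvdw(z)
        if r <= 0 or pt.GetRcovalent(z) <= 0:
            raise UnsupportedElementError(f"no radius parameters for {atom.GetSymbol()}")
        radii[atom.GetIdx()] = r
    areas = 4.0 * math.pi * radii**2
    for bond in molh.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        zi = molh.GetAtomWithIdx(i).GetAtomicNum()
        zj = molh.GetAtomWithIdx(j).GetAtomicNum()
        scale = _BOND_ORDER_SCALE.get(bond.GetBondTypeAsDouble(), 1.0)
        d = (pt.GetRcovalent(zi) + pt.GetRcovalent(zj)) * scale
        areas[i] -= _sphere_cap_hidden(radii[i], radii[j], d)
        areas[j] -= _sphere_cap_hidden(radii[j], radii[i], d)
    areas = np.maximum(areas, 0.0)
    heavy, hmap = _heavy_atom_hydrogen_map(molh)
    summed = {i: areas[i] for i in heavy}
    for h_idx, parent in hmap.items():
        summed[parent] += areas[h_idx]
    per_heavy = np.array([summed[i] for i in heavy])
    return AtomSurface(areas=per_heavy)


def fingerprint(mol: Molecule, n_bits: int = 1024, max_path: int = 7) -> Fingerprint:
    """Hashed linear-path fingerprint (paths of 1..max_path bonds)."""
    bv = Chem.RDKFingerprint(
        mol.rdmol,
        minPath=1,
        maxPath=max_path,
        fpSize=n_bits,
        branchedPaths=False,
    )
    return Fingerprint(bits=frozenset(bv.GetOnBits()), n_bits=n_bits, max_path=max_path)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B|; 1.0 for two empty vectors."""
    if not a.compatible_with(b):
        raise ValueError(
            f"incompatible fingerprints: ({a.n_bits}, {a.max_path}) vs ({b.n_bits}, {b.max_path})"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union
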
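"""Independent reference implementations used only by the test suite.

These deliberately share no code with the package: a from-scratch
Gasteiger–Marsili charge iteration, a numerical dot-surface area, an
exhaustive simple-path enumeration, explicit leave-one-out refits and a
normal-equations least-squares solve.
"""

from __future__ import annotations

import itertools

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

# Gasteiger–Marsili electronegativity parameters (a, b, c) by element and
# hybridisation, from the original parameterisation.
_GM_PARAMS = {
    ("H", None): (7.17, 6.24, -0.56),
    ("C", "sp3"): (7.98, 9.18, 1.88),
    ("C", "sp2"): (8.79, 9.32, 1.51),
    ("C", "sp"): (10.39, 9.45, 0.73),
    ("N", "sp3"): (11.54, 10.82, 1.36),
    ("N", "sp2"): (12.87, 11.15, 0.85),
    ("N", "sp"): (15.68, 11.70, -0.27),
    ("O", "sp3"): (14.18, 12.92, 1.39),
    ("O", "sp2"): (17.07, 13.79, 0.47),
    ("F", None): (14.66, 13.85, 2.31),
    ("Cl", None): (11.00, 9.69, 1.35),
    ("Br", None): (10.08, 8.47, 1.16),
    ("I", None): (9.90, 7.96, 0.96),
    ("S", None): (10.14, 9.13, 1.38),
}
_H_CATION_CHI = 20.02


def _gm_params(atom: Chem.Atom):
    sym = atom.GetSymbol()
    if (sym, None) in _GM_PARAMS:
        return _GM_PARAMS[(sym, None)]
    hyb = {
        Chem.HybridizationType.SP3: "sp3",
        Chem.HybridizationType.SP2: "sp2",
        Chem.HybridizationType.SP: "sp",
    }.get(atom.GetHybridization(), "sp3")
    if atom.GetIsAromatic():
        hyb = "sp2"
    return _GM_PARAMS[(sym, hyb)]


def gasteiger_charges(
    smiles: str, n_iter: int = 6, sum_hydrogens: bool = True
) -> dict[str, float]:
    """PEOE charges by direct iteration; heavy atoms with H summed in.

    Returns {atom_index_symbol: charge} keyed like "0:O" for the heavy
    atoms of the molecule (explicit-H charges folded into the parent).
    """
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    atoms = list(mol.GetAtoms())
    params = [_gm_params(a) for a in atoms]
    q = np.array([float(a.GetFormalCharge()) for a in atoms])
    for k in range(1, n_iter + 1):
        chi = np.array([a_ + b_ * qi + c_ * qi * qi for (a_, b_, c_), qi in zip(params, q)])
        damp = 0.5**k
        dq = np.zeros_like(q)
        for bond in mol.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if chi[j] > chi[i]:
                donor, acceptor = i, j
            else:
                donor, acceptor = j, i
            a_, b_, c_ = params[donor]
            chi_plus = _H_CATION_CHI if atoms[donor].GetSymbol() == "H" else a_ + b_ + c_
            transfer = (chi[acceptor] - chi[donor]) / chi_plus * damp
            dq[donor] += transfer
            dq[acceptor] -= transfer
        q = q + dq
    out = {}
    for atom in atoms:
        if atom.GetAtomicNum() == 1:
            continue
        total = q[atom.GetIdx()]
        if sum_hydrogens:
            total += sum(
                q[n.GetIdx()] for n in atom.GetNeighbors() if n.GetAtomicNum() == 1
            )
        out[f"{atom.GetIdx()}:{atom.GetSymbol()}"] = float(total)
    return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.c_[np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]


def dot_surface_areas(smiles: str, seed: int = 2024, n_dots: int = 1024) -> np.ndarray:
    """Numerical per-heavy-atom vdW surface (Å²) on a fixed 3D embedding.

    Places ``n_dots`` points on each atom's vdW sphere and counts those
    outside every other sphere; hydrogen areas are summed onto their
    heavy atom. Uses the same periodic-table radii as the package but a
    completely different (numerical, conformer-based) algorithm.
    """
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(mol, params) == 0
    AllChem.MMFFOptimizeMolecule(mol)
    conf = mol.GetConformer()
    pt = Chem.GetPeriodicTable()
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    radii = np.array([pt.GetRvdw(a.GetAtomicNum()) for a in mol.GetAtoms()])
    dots = _fibonacci_sphere(n_dots)
    areas = np.zeros(mol.GetNumAtoms())
    for i in range(mol.GetNumAtoms()):
        pts = coords[i] + radii[i] * dots
        exposed = np.ones(n_dots, dtype=bool)
        for j in range(mol.GetNumAtoms()):
            if j == i:
                continue
            exposed &= np.linalg.norm(pts - coords[j], axis=1) >= radii[j]
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.mean()
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() != 1]
    grouped = {i: areas[i] for i in heavy}
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            grouped[atom.GetNeighbors()[0].GetIdx()] += areas[atom.GetIdx()]
    return np.array([grouped[i] for i in heavy])


def longest_acyclic_single_bond_path(smiles: str) -> int:
    """Exhaustive enumeration of simple paths over acyclic single bonds."""
    mol = Chem.MolFromSmiles(smiles)
    edges = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx())
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE
        and not b.GetIsAromatic()
        and not b.IsInRing()
    ]
    adj: dict[int, set[int]] = {}
    for i, j in edges:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)

    best = 0

    def dfs(node: int, visited: set[int], length: int):
        nonlocal best
        best = max(best, length)
        for nxt in adj.get(node, ()):
            if nxt not in visited:
                dfs(nxt, visited | {nxt}, length + 1)

    for start in adj:
        dfs(start, {start}, 0)
    return best


def loo_q2_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    """q² from n explicit leave-one-out refits."""
    n = len(y)
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        xd = np.column_stack([np.ones(mask.sum()), x[mask]])
        beta, *_ = np.linalg.lstsq(xd, y[mask], rcond=None)
        pred = np.concatenate([[1.0], x[i]]) @ beta
        press += (y[i] - pred) ** 2
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / sst


def normal_equations_fit(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """[intercept, coefficients] via the normal equations."""
    xd = np.column_stack([np.ones(len(y)), x])
    return np.linalg.solve(xd.T @ xd, xd.T @ y)


def enumerate_linear_paths(smiles: str, max_path: int = 7) -> set[tuple]:
    """Canonical forms of all simple bond paths up to ``max_path`` bonds."""
    mol = Chem.MolFromSmiles(smiles)
    paths = set()
    for length in range(1, max_path + 1):
        for path in Chem.FindAllPathsOfLengthN(mol, length, useBonds=True):
            atoms = []
            bonds = []
            for bidx in path:
                bonds.append(mol.GetBondWithIdx(bidx))
            paths.add(tuple(sorted(b.GetBondType() for b in bonds)))
    return paths
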
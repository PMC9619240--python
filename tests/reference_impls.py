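"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own code paths for the quantity
they check: orbit counting goes through graph automorphisms (Burnside)
instead of canonical-SMILES dedup, pairing is a literal scan-the-matrix
simulation of the greedy rule, and the RMSD oracle searches rotation space
numerically instead of solving it in closed form.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import List, Sequence, Tuple

import networkx as nx
import numpy as np
from networkx.algorithms.isomorphism import GraphMatcher, categorical_edge_match, categorical_node_match
from rdkit import Chem
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def burnside_substitution_orbits(smiles: str) -> int:
    """Number of distinct substitution patterns over all subsets of aromatic
    C-H sites, counted via Burnside's lemma on the molecular-graph
    automorphism group (no SMILES canonicalization involved)."""
    mol = Chem.MolFromSmiles(smiles)
    graph = nx.Graph()
    for atom in mol.GetAtoms():
        graph.add_node(atom.GetIdx(), element=atom.GetAtomicNum(), n_h=atom.GetTotalNumHs())
    for bond in mol.GetBonds():
        graph.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order=str(bond.GetBondType()))
    sites = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIsAromatic() and a.GetAtomicNum() == 6 and a.GetTotalNumHs() == 1
    ]
    matcher = GraphMatcher(
        graph,
        graph,
        node_match=categorical_node_match(["element", "n_h"], [0, 0]),
        edge_match=categorical_edge_match("order", ""),
    )
    total = 0
    n_autos = 0
    for mapping in matcher.isomorphisms_iter():
        n_autos += 1
        total += 2 ** _n_cycles_on(mapping, sites)
    assert total % n_autos == 0
    return total // n_autos


def _n_cycles_on(mapping: dict, sites: Sequence[int]) -> int:
    seen = set()
    cycles = 0
    for start in sites:
        if start in seen:
            continue
        cycles += 1
        node = start
        while node not in seen:
            seen.add(node)
            node = mapping[node]
    return cycles


def greedy_pairing_by_scan(
    matrix: np.ndarray, keys_a: List[str], keys_b: List[str]
) -> List[Tuple[str, str, float]]:
    """Literal simulation of the maximum-similarity pairing rule: rescan the
    whole matrix each round for the best unused cell, unordered-pair
    lexicographic tie-break."""
    m = matrix.copy().astype(float)
    n_a, n_b = m.shape
    used_a = set()
    used_b = set()
    pairs = []
    for _ in range(min(n_a, n_b)):
        best = None
        for i in range(n_a):
            if i in used_a:
                continue
            for j in range(n_b):
                if j in used_b:
                    continue
                key = tuple(sorted((keys_a[i], keys_b[j])))
                cand = (-m[i, j], key, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        used_a.add(i)
        used_b.add(j)
        pairs.append((keys_a[i], keys_b[j], float(m[i, j])))
    return pairs


def rmsd_by_rotation_search(coords_a, coords_b, n_grid: int = 14) -> float:
    """Minimal RMSD over rotations found by an Euler-angle grid scan followed
    by local polish; independent of the closed-form Kabsch solution."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    n = a.shape[0]

    def rmsd_for(rotvec):
        rotated = Rotation.from_rotvec(rotvec).apply(b)
        return float(np.sqrt(np.mean(np.sum((rotated - a) ** 2, axis=1))))

    best_val = np.inf
    best_vec = np.zeros(3)
    angles = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    betas = np.linspace(0, np.pi, n_grid)
    for alpha, beta, gamma in product(angles, betas, angles):
        vec = Rotation.from_euler("zyz", [alpha, beta, gamma]).as_rotvec()
        val = rmsd_for(vec)
        if val < best_val:
            best_val, best_vec = val, vec
    res = minimize(rmsd_for, best_vec, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12})
    return float(min(best_val, res.fun))


def bitmask_mutants(smiles: str, ops: Sequence[str], max_sites: int) -> set:
    """Brute-force mutant enumeration: iterate bitmasks over aromatic C-H
    sites up to the given popcount, apply each op assignment, dedup by
    canonical SMILES. Written independently of the package's editor."""
    mol = Chem.MolFromSmiles(smiles)
    parent = Chem.MolToSmiles(mol)
    sites = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIsAromatic() and a.GetAtomicNum() == 6 and a.GetTotalNumHs() == 1
    ]
    attach_smiles = {"F": "F", "CN": "C#N", "OMe": "OC", "NMe2": "N(C)C"}
    out = set()
    n = len(sites)
    for mask in range(1, 2**n):
        chosen = [sites[i] for i in range(n) if mask >> i & 1]
        if not 1 <= len(chosen) <= max_sites:
            continue
        for assignment in product(ops, repeat=len(chosen)):
            rw = Chem.RWMol(mol)
            for site, op in zip(chosen, assignment):
                atom = rw.GetAtomWithIdx(site)
                atom.SetNumExplicitHs(0)
                if op == "N":
                    atom.SetAtomicNum(7)
                else:
                    frag = Chem.MolFromSmiles(attach_smiles[op])
                    amap = {}
                    for fa in frag.GetAtoms():
                        amap[fa.GetIdx()] = rw.AddAtom(Chem.Atom(fa.GetAtomicNum()))
                    for fb in frag.GetBonds():
                        rw.AddBond(amap[fb.GetBeginAtomIdx()], amap[fb.GetEndAtomIdx()], fb.GetBondType())
                    rw.AddBond(site, amap[0], Chem.BondType.SINGLE)
            try:
                product_mol = rw.GetMol()
                Chem.SanitizeMol(product_mol)
            except Exception:
                continue
            smi = Chem.MolToSmiles(product_mol)
            if smi != parent:
                out.add(smi)
    return out
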
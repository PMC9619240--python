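"""Structural mutation operators over aromatic C-H sites.

Two mutation families act on a molecule's aromatic C-H positions:

* aromatic N swap: the whole aC-H unit is replaced by an aromatic N
  (benzene -> pyridine);
* terminal substitution: the aromatic H is replaced by a small donor or
  acceptor group G in {F, CN, OMe, NMe2}.

The ten named operators Sub1..Sub10 combine these: Sub1/Sub2 are the slow
(one site) and fast (up to two sites) N swaps; Sub3-Sub6 substitute a
single group (F, CN, OMe, NMe2); Sub7-Sub10 draw each site's group from a
two-group mixture (F|OMe, F|NMe2, CN|OMe, CN|NMe2). Offspring failing
sanitization are discarded; products are deduplicated by canonical SMILES.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from rdkit import Chem

from .chem import MoleculeRecord, aromatic_ch_sites, mol_from_smiles
from .fragments import ConfigError, Library

GROUPS = ("F", "CN", "OMe", "NMe2")

_SPEC_TABLE: Dict[str, Tuple[str, Tuple[str, ...], int]] = {
    "Sub1": ("aromatic_N_swap", (), 1),
    "Sub2": ("aromatic_N_swap", (), 2),
    "Sub3": ("terminal_substitution", ("F",), 1),
    "Sub4": ("terminal_substitution", ("CN",), 1),
    "Sub5": ("terminal_substitution", ("OMe",), 1),
    "Sub6": ("terminal_substitution", ("NMe2",), 1),
    "Sub7": ("terminal_substitution", ("F", "OMe"), 1),
    "Sub8": ("terminal_substitution", ("F", "NMe2"), 1),
    "Sub9": ("terminal_substitution", ("CN", "OMe"), 1),
    "Sub10": ("terminal_substitution", ("CN", "NMe2"), 1),
}


@dataclass(frozen=True)
class MutationSpec:
    """One of the ten operators: its family, group mixture and site budget."""

    label: str
    kind: str
    groups: Tuple[str, ...]
    max_sites_per_offspring: int

    def __post_init__(self) -> None:
        if self.kind not in ("aromatic_N_swap", "terminal_substitution"):
            raise ConfigError(f"unknown mutation kind: {self.kind!r}")
        if self.kind == "terminal_substitution" and not self.groups:
            raise ConfigError("terminal substitution needs at least one group")
        for g in self.groups:
            if g not in GROUPS:
                raise ConfigError(f"unknown substituent group {g!r}; choose from {GROUPS}")
        if self.max_sites_per_offspring < 1:
            raise ConfigError("max_sites_per_offspring must be >= 1")

    @classmethod
    def from_label(cls, label: str) -> "MutationSpec":
        if label not in _SPEC_TABLE:
            raise ConfigError(
                f"unknown mutation label {label!r}; valid labels: {', '.join(_SPEC_TABLE)}"
            )
        kind, groups, max_sites = _SPEC_TABLE[label]
        return cls(label=label, kind=kind, groups=groups, max_sites_per_offspring=max_sites)


def _apply_edit(mol: Chem.Mol, edits: Sequence[Tuple[int, str]]) -> str | None:
    """Apply (site, op) edits on a copy; op is 'N' for the aromatic swap or a group name.

    Returns the canonical SMILES of the sanitized product, or None if
    sanitization fails.
    """
    rw = Chem.RWMol(mol)
    for site, op in edits:
        atom = rw.GetAtomWithIdx(site)
        if op == "N":
            atom.SetAtomicNum(7)
            atom.SetNumExplicitHs(0)
            continue
        atom.SetNumExplicitHs(0)
        if op == "F":
            f = rw.AddAtom(Chem.Atom(9))
            rw.AddBond(site, f, Chem.BondType.SINGLE)
        elif op == "CN":
            c = rw.AddAtom(Chem.Atom(6))
            n = rw.AddAtom(Chem.Atom(7))
            rw.AddBond(site, c, Chem.BondType.SINGLE)
            rw.AddBond(c, n, Chem.BondType.TRIPLE)
        elif op == "OMe":
            o = rw.AddAtom(Chem.Atom(8))
            c = rw.AddAtom(Chem.Atom(6))
            rw.AddBond(site, o, Chem.BondType.SINGLE)
            rw.AddBond(o, c, Chem.BondType.SINGLE)
        elif op == "NMe2":
            n = rw.AddAtom(Chem.Atom(7))
            c1 = rw.AddAtom(Chem.Atom(6))
            c2 = rw.AddAtom(Chem.Atom(6))
            rw.AddBond(site, n, Chem.BondType.SINGLE)
            rw.AddBond(n, c1, Chem.BondType.SINGLE)
            rw.AddBond(n, c2, Chem.BondType.SINGLE)
        else:  # pragma: no cover
            raise ValueError(f"unknown edit op {op!r}")
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return Chem.MolToSmiles(out)


def _site_ops(spec: MutationSpec) -> Tuple[str, ...]:
    return ("N",) if spec.kind == "aromatic_N_swap" else spec.groups


def single_site_mutants(smiles: str, spec: MutationSpec) -> Set[str]:
    """All products with exactly one aromatic C-H site mutated, deduplicated."""
    mol = mol_from_smiles(smiles)
    parent = Chem.MolToSmiles(mol)
    out: Set[str] = set()
    for site in aromatic_ch_sites(smiles):
        for op in _site_ops(spec):
            child = _apply_edit(mol, [(site, op)])
            if child is not None and child != parent:
                out.add(child)
    return out


def multi_site_mutants(smiles: str, spec: MutationSpec) -> Set[str]:
    """Union of products with 1..max_sites sites mutated simultaneously."""
    mol = mol_from_smiles(smiles)
    parent = Chem.MolToSmiles(mol)
    sites = aromatic_ch_sites(smiles)
    ops = _site_ops(spec)
    out: Set[str] = set()
    for k in range(1, spec.max_sites_per_offspring + 1):
        for combo in combinations(sites, k):
            for assignment in product(ops, repeat=k):
                child = _apply_edit(mol, list(zip(combo, assignment)))
                if child is not None and child != parent:
                    out.add(child)
    return out


def enumerate_substitution_subsets(smiles: str, group: str = "F") -> Tuple[int, Set[str]]:
    """Exhaustive subset mode: substitute every subset of aromatic C-H sites.

    Returns ``(n_labeled_patterns, unique_canonical_set)`` where the count
    includes the empty subset (the parent itself) and the set is the
    canonical dedup of all products. For biphenyl with F this maps the
    2^10 = 1024 position-labeled patterns onto 210 distinct molecules.
    """
    mol = mol_from_smiles(smiles)
    sites = aromatic_ch_sites(smiles)
    n_labeled = 0
    unique: Set[str] = set()
    for k in range(len(sites) + 1):
        for combo in combinations(sites, k):
            n_labeled += 1
            child = _apply_edit(mol, [(s, group) for s in combo])
            if child is not None:
                unique.add(child)
    return n_labeled, unique


def offspring_library(parents: Library, spec: MutationSpec, cap: int = 1000, seed: int = 0) -> Library:
    """Next-generation library: parents plus all their mutants, capped.

    Parents are always retained (the accumulation property driving the
    optimal-molecule counts); if parents plus unique offspring exceed the
    cap, offspring are down-sampled uniformly with the given seed.
    """
    if len(parents) == 0:
        raise ConfigError("offspring_library needs a non-empty parent set")
    if cap < len(parents):
        raise ConfigError(
            f"cap {cap} is smaller than the parent count {len(parents)}"
        )
    parent_smiles = parents.smiles()
    children: Dict[str, Tuple[str, str]] = {}
    for p in parent_smiles:
        for child in sorted(multi_site_mutants(p, spec)):
            if child not in children and child not in parents:
                children[child] = (p, spec.label)
    child_list = sorted(children)
    n_room = cap - len(parent_smiles)
    if len(child_list) > n_room:
        rng = np.random.default_rng(seed)
        child_list = sorted(rng.choice(child_list, size=n_room, replace=False))
    lib = Library(generation=parents.generation + 1, cap=cap)
    for p in parent_smiles:
        rec = parents.records[p]
        lib.add(
            MoleculeRecord(
                p,
                generation_born=rec.generation_born,
                parent_smiles=rec.parent_smiles,
                mutation_label=rec.mutation_label,
            )
        )
    for child in child_list:
        parent, label = children[child]
        lib.add(
            MoleculeRecord(
                child,
                generation_born=parents.generation + 1,
                parent_smiles=parent,
                mutation_label=label,
            )
        )
    return lib
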
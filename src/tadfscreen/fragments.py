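"""Donor-acceptor fragment handling and generation-0 library construction.

The initial library is built by combinatorial enumeration: every donor is
joined to every acceptor through a single bond between their attachment
points (encoded as a ``[*]`` dummy atom, exactly one per fragment). The
shipped fragment pools are curated stand-ins spanning the usual TADF
chemotypes — carbazole / phenoxazine / phenothiazine / acridine /
diarylamine donors and cyano / sulfonyl / triazine / carbonyl aromatic
acceptors — not any particular published fragment set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import MoleculeRecord, ParseError, canonicalize


class FragmentArityError(ValueError):
    """Raised when a fragment does not carry exactly one attachment point."""


class ConfigError(ValueError):
    """Raised on invalid run parameters (bad cap, bad fractions, ...)."""


# ---------------------------------------------------------------------------
# Shipped fragment pools (synthetic stand-in set; [*] marks the attachment).
# ---------------------------------------------------------------------------

DONOR_POOL: List[str] = [
    "[*]n1c2ccccc2c2ccccc21",                            # carbazol-9-yl
    "[*]n1c2ccc(C)cc2c2cc(C)ccc21",                      # 3,6-dimethylcarbazolyl
    "[*]n1c2ccc(C(C)(C)C)cc2c2cc(C(C)(C)C)ccc21",        # 3,6-di-tBu-carbazolyl
    "[*]n1c2ccc(C)cc2c2ccccc21",                         # 3-methylcarbazolyl
    "[*]n1c2ccccc2c2cc(-c3ccccc3)ccc21",                 # 3-phenylcarbazolyl
    "[*]n1c2ccc(-c3ccccc3)cc2c2cc(-c3ccccc3)ccc21",      # 3,6-diphenylcarbazolyl
    "[*]N(c1ccccc1)c1ccccc1",                            # diphenylamino
    "[*]N(c1ccc(C)cc1)c1ccc(C)cc1",                      # di(p-tolyl)amino
    "[*]N(c1ccccc1)c1ccc(C)cc1",                         # phenyl(p-tolyl)amino
    "[*]N(C)c1ccccc1",                                   # N-methylanilino
    "[*]N1c2ccccc2Oc2ccccc21",                           # phenoxazin-10-yl
    "[*]N1c2ccc(C)cc2Oc2cc(C)ccc21",                     # dimethylphenoxazinyl
    "[*]N1c2ccccc2Sc2ccccc21",                           # phenothiazin-10-yl
    "[*]N1c2ccc(C)cc2Sc2cc(C)ccc21",                     # dimethylphenothiazinyl
    "[*]N1c2ccccc2C(C)(C)c2ccccc21",                     # 9,9-dimethylacridin-10-yl
    "[*]N1c2ccccc2C(c2ccccc2)(c2ccccc2)c2ccccc21",       # 9,9-diphenylacridin-10-yl
    "[*]N1c2ccccc2Cc2ccccc21",                           # 9,10-dihydroacridin-10-yl
    "[*]c1ccc(N(c2ccccc2)c2ccccc2)cc1",                  # 4-(diphenylamino)phenyl
    "[*]c1cccc(N(c2ccccc2)c2ccccc2)c1",                  # 3-(diphenylamino)phenyl
    "[*]c1ccc(n2c3ccccc3c3ccccc32)cc1",                  # 4-(carbazol-9-yl)phenyl
    "[*]c1ccc(N2c3ccccc3Oc3ccccc32)cc1",                 # 4-(phenoxazinyl)phenyl
    "[*]c1ccc(N2c3ccccc3Sc3ccccc32)cc1",                 # 4-(phenothiazinyl)phenyl
    "[*]c1ccc(N2c3ccccc3C(C)(C)c3ccccc32)cc1",           # 4-(dimethylacridinyl)phenyl
    "[*]c1ccc2c(c1)[nH]c1ccccc12",                       # carbazol-2-yl (C-linked)
    "[*]c1ccc2c(c1)oc1ccccc12",                          # dibenzofuran-2-yl
    "[*]c1ccc2c(c1)sc1ccccc12",                          # dibenzothiophen-2-yl
    "[*]c1ccc(OC)cc1",                                   # 4-methoxyphenyl
    "[*]c1ccc(N(C)C)cc1",                                # 4-(dimethylamino)phenyl
    "[*]c1ccc(-c2ccc(N(c3ccccc3)c3ccccc3)cc2)cc1",       # 4'-(diphenylamino)biphenylyl
    "[*]N1CCN(c2ccccc2)CC1",                             # 4-phenylpiperazin-1-yl
]

ACCEPTOR_POOL: List[str] = [
    "[*]c1ccc(C#N)cc1",                              # 4-cyanophenyl
    "[*]c1cccc(C#N)c1",                              # 3-cyanophenyl
    "[*]c1ccccc1C#N",                                # 2-cyanophenyl
    "[*]c1ccc(-c2ccc(C#N)cc2)cc1",                   # 4'-cyanobiphenylyl
    "[*]c1cc(C#N)cc(C#N)c1",                         # 3,5-dicyanophenyl
    "[*]c1ccc(C#N)c(C#N)c1",                         # 3,4-dicyanophenyl
    "[*]c1ccc(S(C)(=O)=O)cc1",                       # 4-(methylsulfonyl)phenyl
    "[*]c1ccc(S(=O)(=O)c2ccccc2)cc1",                # 4-(phenylsulfonyl)phenyl
    "[*]c1cccc(S(=O)(=O)c2ccccc2)c1",                # 3-(phenylsulfonyl)phenyl
    "[*]c1ccc(S(=O)(=O)C(F)(F)F)cc1",                # 4-(triflylsulfonyl)phenyl
    "[*]c1ccc2c(c1)S(=O)(=O)c1ccccc1-2",             # dibenzothiophene-S,S-dioxide-2-yl
    "[*]c1ccc(C(=O)c2ccccc2)cc1",                    # benzophenon-4-yl
    "[*]c1cccc(C(=O)c2ccccc2)c1",                    # benzophenon-3-yl
    "[*]c1ccc(C(C)=O)cc1",                           # 4-acetylphenyl
    "[*]c1ccc(C(=O)OC)cc1",                          # 4-(methoxycarbonyl)phenyl
    "[*]c1ccc2c(c1)C(=O)c1ccccc1C2=O",               # anthraquinon-2-yl
    "[*]c1ccc2c(c1)C(=O)c1ccccc1-2",                 # fluorenon-2-yl
    "[*]c1ccc(C(F)(F)F)cc1",                         # 4-(trifluoromethyl)phenyl
    "[*]c1cc(C(F)(F)F)cc(C(F)(F)F)c1",               # 3,5-bis(trifluoromethyl)phenyl
    "[*]c1ccc(P(=O)(c2ccccc2)c2ccccc2)cc1",          # 4-(diphenylphosphoryl)phenyl
    "[*]c1ccc([N+](=O)[O-])cc1",                     # 4-nitrophenyl
    "[*]c1ccc(F)cc1",                                # 4-fluorophenyl
    "[*]c1ccc(F)c(F)c1",                             # 3,4-difluorophenyl
    "[*]c1ccncc1",                                   # pyridin-4-yl
    "[*]c1cccnc1",                                   # pyridin-3-yl
    "[*]c1ccccn1",                                   # pyridin-2-yl
    "[*]c1cncnc1",                                   # pyrimidin-5-yl
    "[*]c1ccnc(-c2ccccc2)n1",                        # 2-phenylpyrimidin-4-yl
    "[*]c1nc(-c2ccccc2)nc(-c2ccccc2)n1",             # 4,6-diphenyl-1,3,5-triazin-2-yl
    "[*]c1ccc(-c2nc(-c3ccccc3)nc(-c3ccccc3)n2)cc1",  # triazinylphenyl
    "[*]c1cnc2ccccc2n1",                             # quinoxalin-2-yl
    "[*]c1ccc2nccnc2c1",                             # quinoxalin-6-yl
    "[*]c1ccc2ncccc2c1",                             # quinolin-6-yl
    "[*]c1ccc2nc3ccccc3nc2c1",                       # phenazin-2-yl
    "[*]c1nnc(-c2ccccc2)o1",                         # 5-phenyl-1,3,4-oxadiazol-2-yl
    "[*]c1ccc(-c2nnc(-c3ccccc3)o2)cc1",              # oxadiazolylphenyl
    "[*]c1nnc(-c2ccccc2)s1",                         # 5-phenyl-1,3,4-thiadiazol-2-yl
    "[*]c1nc2ccccc2o1",                              # benzoxazol-2-yl
    "[*]c1nc2ccccc2s1",                              # benzothiazol-2-yl
    "[*]c1ccc(-c2nc3ccccc3s2)cc1",                   # benzothiazolylphenyl
    "[*]c1ccc(-c2nc3ccccc3o2)cc1",                   # benzoxazolylphenyl
    "[*]c1ccc(C#N)cc1F",                             # 2-fluoro-4-cyanophenyl
    "[*]c1ccc(S(=O)(=O)c2ccccc2)cc1C",               # 2-methyl-4-(phenylsulfonyl)phenyl
]


def _attachment_indices(mol: Chem.Mol) -> List[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]


def validate_fragment(smiles: str) -> str:
    """Parse a fragment and require exactly one attachment dummy; returns canonical form."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable fragment SMILES: {smiles!r}")
    n_att = len(_attachment_indices(mol))
    if n_att != 1:
        raise FragmentArityError(
            f"fragment must carry exactly one attachment point, got {n_att}: {smiles!r}"
        )
    return Chem.MolToSmiles(mol)


@dataclass
class FragmentSet:
    """Donor and acceptor fragments, each with a single attachment point."""

    donors: List[str]
    acceptors: List[str]
    name: str = "unnamed"

    def __post_init__(self) -> None:
        self.donors = _validate_pool(self.donors, "donor")
        self.acceptors = _validate_pool(self.acceptors, "acceptor")


def _validate_pool(pool: Iterable[str], role: str) -> List[str]:
    seen: dict[str, None] = {}
    for smi in pool:
        can = validate_fragment(smi)
        if can in seen:
            raise ValueError(f"duplicate {role} fragment after canonicalization: {smi!r}")
        seen[can] = None
    return list(seen)


@dataclass
class Library:
    """A generation-indexed molecule set with dedup-by-canonical-SMILES semantics."""

    generation: int = 0
    records: Dict[str, MoleculeRecord] = field(default_factory=dict)
    cap: int = 1000

    def add(self, record: MoleculeRecord) -> bool:
        """Insert unless the canonical SMILES is already present; True if added."""
        if record.smiles_canonical in self.records:
            return False
        self.records[record.smiles_canonical] = record
        return True

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, smiles: str) -> bool:
        return smiles in self.records

    def __iter__(self) -> Iterator[str]:
        return iter(self.smiles())

    def smiles(self) -> List[str]:
        """Canonical SMILES in sorted order (deterministic iteration order)."""
        return sorted(self.records)

    @classmethod
    def from_smiles(
        cls,
        smiles_list: Iterable[str],
        generation: int = 0,
        cap: int = 1000,
        **record_kwargs,
    ) -> "Library":
        lib = cls(generation=generation, cap=cap)
        for smi in smiles_list:
            lib.add(MoleculeRecord(canonicalize(smi), generation_born=generation, **record_kwargs))
        return lib

    def to_smi(self, path) -> None:
        Path(path).write_text("".join(f"{s}\n" for s in self.smiles()))

    def to_csv(self, path) -> None:
        rows = [
            {
                "smiles": r.smiles_canonical,
                "generation_born": r.generation_born,
                "parent_smiles": r.parent_smiles,
                "mutation_label": r.mutation_label,
            }
            for r in (self.records[s] for s in self.smiles())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def load_smi(path) -> List[str]:
    """Read a .smi file (one record per line, optional whitespace-separated name)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(line.split()[0])
    return out


def couple(donor: str, acceptor: str) -> str:
    """Join two single-attachment fragments with one single bond; canonical product."""
    d = Chem.MolFromSmiles(donor)
    a = Chem.MolFromSmiles(acceptor)
    if d is None or a is None:
        raise ParseError(f"unparsable fragment: {donor if d is None else acceptor!r}")
    for frag, smi in ((d, donor), (a, acceptor)):
        if len(_attachment_indices(frag)) != 1:
            raise FragmentArityError(
                f"fragment must carry exactly one attachment point: {smi!r}"
            )
    combo = Chem.RWMol(Chem.CombineMols(d, a))
    dummies = _attachment_indices(combo)
    neighbors = [combo.GetAtomWithIdx(i).GetNeighbors()[0].GetIdx() for i in dummies]
    combo.AddBond(neighbors[0], neighbors[1], Chem.BondType.SINGLE)
    for idx in sorted(dummies, reverse=True):
        combo.RemoveAtom(idx)
    product = combo.GetMol()
    try:
        Chem.SanitizeMol(product)
    except Exception as exc:
        raise ParseError(f"coupling product failed sanitization: {donor} + {acceptor}: {exc}")
    return Chem.MolToSmiles(product)


def enumerate_da_library(fragments: FragmentSet, cap: int = 1000, seed: int = 0) -> Library:
    """Form all donor x acceptor couplings, dedup, and cap by seeded uniform sampling."""
    if cap < 1:
        raise ConfigError(f"library cap must be >= 1, got {cap}")
    if not fragments.donors or not fragments.acceptors:
        raise ConfigError("fragment set must contain at least one donor and one acceptor")
    products: dict[str, None] = {}
    for d in fragments.donors:
        for a in fragments.acceptors:
            products[couple(d, a)] = None
    unique = sorted(products)
    if len(unique) > cap:
        rng = np.random.default_rng(seed)
        unique = sorted(rng.choice(unique, size=cap, replace=False))
    lib = Library(generation=0, cap=cap)
    for smi in unique:
        lib.add(MoleculeRecord(smi, generation_born=0, mutation_label="enumeration"))
    return lib


def fixture_fragments(n_donors: int = 30, n_acceptors: int = 43, seed: int = 0) -> FragmentSet:
    """Deterministic sample from the shipped donor/acceptor pools.

    The pools are a synthetic stand-in fragment set covering typical TADF
    donor and acceptor chemotypes.
    """
    if n_donors > len(DONOR_POOL) or n_acceptors > len(ACCEPTOR_POOL):
        raise ValueError(
            f"requested {n_donors} donors / {n_acceptors} acceptors but pools hold "
            f"{len(DONOR_POOL)} / {len(ACCEPTOR_POOL)}"
        )
    rng = np.random.default_rng(seed)
    donors = [DONOR_POOL[i] for i in sorted(rng.choice(len(DONOR_POOL), n_donors, replace=False))]
    acceptors = [
        ACCEPTOR_POOL[i] for i in sorted(rng.choice(len(ACCEPTOR_POOL), n_acceptors, replace=False))
    ]
    return FragmentSet(donors=donors, acceptors=acceptors, name=f"fixture-seed{seed}")
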
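"""Molecular primitives for donor-acceptor emitter screening.

Everything downstream (library enumeration, mutation, surrogate modelling,
similarity analysis) is keyed on canonical SMILES produced here, so this
module owns parsing, canonicalization, aromatic-site inventory, circular
fingerprints, Tanimoto similarity, Murcko scaffold decomposition and
synthetic-accessibility scoring.
"""

from __future__ import annotations

import os
import sys
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd
from rdkit import Chem, RDConfig
from rdkit import RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

# Conventional ECFP4 configuration: radius-2 atom environments hashed
# into a fixed-length binary vector.
FP_RADIUS = 2
FP_NBITS = 2048

_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_NBITS)


class ParseError(ValueError):
    """Raised when a SMILES string cannot be parsed or sanitized."""


class ScaffoldError(ValueError):
    """Raised when a molecule has no ring scaffold."""


class EmptyLibraryError(ValueError):
    """Raised when an aggregate is requested over an empty library."""


class PropertySource(str, Enum):
    COMPUTED = "computed"
    PREDICTED = "predicted"
    ORACLE = "oracle"


@dataclass
class MoleculeRecord:
    """One library member, keyed by canonical SMILES, with provenance.

    ``gap_est`` is the singlet-triplet gap ΔE_ST in eV; ``e_s1`` the
    vertical S1 excitation energy in eV; ``sas`` the synthetic
    accessibility score (≈1 easiest … ≈10 hardest).
    """

    smiles_canonical: str
    generation_born: int = 0
    parent_smiles: Optional[str] = None
    mutation_label: Optional[str] = None
    gap_est: Optional[float] = None
    e_s1: Optional[float] = None
    property_source: Optional[PropertySource] = None
    sas: Optional[float] = None

    def __post_init__(self) -> None:
        if self.generation_born < 0:
            raise ValueError("generation_born must be non-negative")
        if self.gap_est is not None and self.gap_est < 0:
            raise ValueError("gap_est must be >= 0 eV")
        if self.e_s1 is not None and self.e_s1 <= 0:
            raise ValueError("e_s1 must be > 0 eV")


@dataclass(frozen=True)
class SkeletonPair:
    """Murcko scaffold of a molecule in two flavours.

    ``common_core`` keeps element and bond identities; ``generic_core``
    erases them (all atoms carbon-like, all bonds single), so chemically
    different cores sharing a ring topology collapse onto one string.
    """

    common_core: str
    generic_core: str


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse and sanitize, raising :class:`ParseError` on failure."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise ParseError(f"not a SMILES string: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable or unsanitizable SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Return the unique canonical SMILES; equal molecules map to equal strings."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def aromatic_ch_sites(smiles: str) -> list[int]:
    """Atom indices of aromatic carbons bearing exactly one hydrogen.

    These are the substitutable positions (aC-H bonds) for both mutation
    families; ``len(aromatic_ch_sites(s))`` is the molecule's n_aCH.
    """
    mol = mol_from_smiles(smiles)
    return [
        atom.GetIdx()
        for atom in mol.GetAtoms()
        if atom.GetIsAromatic() and atom.GetAtomicNum() == 6 and atom.GetTotalNumHs() == 1
    ]


def mean_aromatic_ch(library: Iterable[str]) -> float:
    """Arithmetic mean of per-molecule aromatic C-H counts over a library."""
    counts = [len(aromatic_ch_sites(s)) for s in library]
    if not counts:
        raise EmptyLibraryError("mean_aromatic_ch over an empty library")
    return float(np.mean(counts))


def fingerprint(smiles: str) -> np.ndarray:
    """Binary circular (ECFP4-style) fingerprint as a uint8 vector of length 2048."""
    return rdkit_fingerprint(smiles, as_numpy=True)


def rdkit_fingerprint(smiles: str, as_numpy: bool = False):
    """Fingerprint as an RDKit ExplicitBitVect (fast bulk similarity) or ndarray."""
    fp = _FP_GEN.GetFingerprint(mol_from_smiles(smiles))
    if not as_numpy:
        return fp
    arr = np.zeros(FP_NBITS, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a∧b| / |a∨b| of two equal-length bit vectors.

    Two all-zero vectors are defined to have similarity 0.0.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 0.0
    return int(np.count_nonzero(a & b)) / union


def skeletons(smiles: str) -> SkeletonPair:
    """Murcko scaffold decomposition into common and generic cores."""
    mol = mol_from_smiles(smiles)
    if mol.GetRingInfo().NumRings() == 0:
        raise ScaffoldError(f"acyclic molecule has no scaffold: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    common = Chem.MolToSmiles(scaffold)
    try:
        generic_mol = MurckoScaffold.MakeScaffoldGeneric(scaffold)
        generic = canonicalize(Chem.MolToSmiles(generic_mol))
    except Exception as exc:  # pragma: no cover - rare valence corner cases
        raise ScaffoldError(f"generic core generation failed for {smiles!r}: {exc}")
    return SkeletonPair(common_core=canonicalize(common), generic_core=generic)


def skeleton_frequencies(library: Iterable[str], core_kind: str = "common") -> pd.DataFrame:
    """Frequency table of Murcko cores over a library.

    Returns a DataFrame with columns ``core`` and ``count`` sorted by
    descending count (ties by core SMILES). Acyclic molecules are skipped;
    their number is recorded in ``df.attrs['n_skipped']`` and warned about.
    """
    if core_kind not in ("common", "generic"):
        raise ValueError("core_kind must be 'common' or 'generic'")
    counts: dict[str, int] = {}
    n_skipped = 0
    for smi in library:
        try:
            pair = skeletons(smi)
        except ScaffoldError:
            n_skipped += 1
            continue
        core = pair.common_core if core_kind == "common" else pair.generic_core
        counts[core] = counts.get(core, 0) + 1
    if n_skipped:
        warnings.warn(f"skeleton_frequencies skipped {n_skipped} acyclic molecule(s)")
    df = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["core", "count"],
    )
    df.attrs["n_skipped"] = n_skipped
    return df


def _load_default_sas() -> Callable[[Chem.Mol], float]:
    sa_dir = os.path.join(RDConfig.RDContribDir, "SA_Score")
    if sa_dir not in sys.path:
        sys.path.append(sa_dir)
    import sascorer  # type: ignore

    return sascorer.calculateScore


_sas_scorer: Optional[Callable[[Chem.Mol], float]] = None


def sas_score(smiles: str, scorer: Optional[Callable[[Chem.Mol], float]] = None) -> float:
    """Synthetic accessibility score on the standard ~1 (easy) … ~10 (hard) scale.

    The default scorer is the fragment-contribution SA score shipped with
    RDKit; an alternative callable (Mol -> float) can be injected.
    """
    global _sas_scorer
    mol = mol_from_smiles(smiles)
    if scorer is None:
        if _sas_scorer is None:
            _sas_scorer = _load_default_sas()
        scorer = _sas_scorer
    return float(scorer(mol))
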
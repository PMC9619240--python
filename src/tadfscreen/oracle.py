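"""Property provision: engine contract, deterministic synthetic oracle,
completeness gating and geometry comparison.

Real excited-state calculations (semi-empirical geometry optimization plus
TD-DFT vertical energies) live behind an adapter contract: anything
callable as ``engine(smiles) -> PropertyResult`` can drive the evolution
loop. The repository ships two engines:

* :class:`SyntheticOracle` — a deterministic structure-sensitive toy model
  used for desk-scale runs and testing. The singlet-triplet gap shrinks
  with the number of donor/acceptor substituents, aromatic nitrogens and
  diarylamine nitrogens; the S1 energy red-shifts with aromatic N and
  strong donors. A small zero-mean pseudo-noise derived from a hash of the
  canonical SMILES makes the landscape non-trivial while staying exactly
  reproducible regardless of evaluation order.
* :class:`TableEngine` — a file-based stub replaying a property CSV, the
  shape an external quantum-chemistry adapter would produce.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.spatial.transform import Rotation

from .chem import canonicalize, mol_from_smiles


class ResultStatus(str, Enum):
    OK = "ok"
    GEOMETRY_FAILED = "geometry_failed"
    PROPERTY_FAILED = "property_failed"


@dataclass(frozen=True)
class PropertyResult:
    """Per-molecule engine output: ΔE_ST (``gap``) and E_S1, both in eV."""

    smiles_canonical: str
    gap: Optional[float]
    e_s1: Optional[float]
    status: ResultStatus = ResultStatus.OK

    def __post_init__(self) -> None:
        if self.status is ResultStatus.OK:
            if self.gap is None or self.e_s1 is None:
                raise ValueError("status=ok requires both gap and e_s1")
            if not (math.isfinite(self.gap) and math.isfinite(self.e_s1)):
                raise ValueError("status=ok requires finite gap and e_s1")


@dataclass(frozen=True)
class CompletenessPolicy:
    """Minimum success fractions required to proceed past an evaluation batch."""

    geometry_min_ratio: float = 0.80
    property_min_ratio: float = 0.90

    def __post_init__(self) -> None:
        for name, v in (
            ("geometry_min_ratio", self.geometry_min_ratio),
            ("property_min_ratio", self.property_min_ratio),
        ):
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


class CompletenessError(RuntimeError):
    """Raised when an evaluation batch falls below the completeness policy."""

    def __init__(
        self,
        geometry_ratio: float,
        property_ratio: float,
        policy: CompletenessPolicy,
        generation: Optional[int] = None,
    ):
        self.geometry_ratio = geometry_ratio
        self.property_ratio = property_ratio
        self.policy = policy
        self.generation = generation
        where = f" at generation {generation}" if generation is not None else ""
        super().__init__(
            f"completeness failure{where}: geometry ok ratio {geometry_ratio:.3f} "
            f"(min {policy.geometry_min_ratio}), property ok ratio {property_ratio:.3f} "
            f"(min {policy.property_min_ratio})"
        )


@dataclass(frozen=True)
class OracleParams:
    """Weights of the synthetic toy model (all energies in eV)."""

    g0: float = 0.70           # baseline singlet-triplet gap
    w_sub: float = 0.06        # per donor/acceptor substituent (F, CN, OMe, NMe2)
    w_n: float = 0.05          # per aromatic ring nitrogen
    w_amine: float = 0.10      # per diarylamine nitrogen
    a_noise: float = 0.05      # amplitude of the hash-derived pseudo-noise
    gap_min: float = 0.01
    gap_max: float = 1.5
    s0: float = 3.30           # baseline vertical S1 energy
    w_red: float = 0.08        # red shift per aromatic N / strong donor
    s_min: float = 1.50
    s_max: float = 4.00


_SMARTS = {
    "F": Chem.MolFromSmarts("[F;$(Fc)]"),
    "CN": Chem.MolFromSmarts("[$([CX2]#[NX1]);$(C(#N)c)]"),
    "OMe": Chem.MolFromSmarts("[CH3][OX2;$(Oc)]"),
    "NMe2": Chem.MolFromSmarts("[CH3][NX3;$(N(C)c)][CH3]"),
    "aromatic_N": Chem.MolFromSmarts("[n]"),
    "diarylamine_N": Chem.MolFromSmarts("[#7;X3;!a](-[a])-[a]"),
}


def count_features(smiles: str) -> dict[str, int]:
    """Structural counts used by the synthetic oracle.

    Symmetric patterns (NMe2, diarylamine) can match in several atom
    orders, so counts are deduplicated on the pivotal atom.
    """
    mol = mol_from_smiles(smiles)

    def n(name: str, pivot: Optional[int] = None) -> int:
        matches = mol.GetSubstructMatches(_SMARTS[name])
        if pivot is None:
            return len(matches)
        return len({m[pivot] for m in matches})

    n_ome = n("OMe")
    n_nme2 = n("NMe2", pivot=1)
    n_diaryl = n("diarylamine_N", pivot=0)
    return {
        "substituents": n("F") + n("CN") + n_ome + n_nme2,
        "aromatic_N": n("aromatic_N"),
        "diarylamine_N": n_diaryl,
        "strong_donors": n_nme2 + n_diaryl,
    }


def _hash_noise(smiles: str, salt: str, amplitude: float) -> float:
    """Zero-mean pseudo-noise in [-amplitude, amplitude], a pure function of the SMILES."""
    digest = hashlib.sha256(f"{smiles}|{salt}".encode()).digest()
    u = int.from_bytes(digest[:8], "big") / 2**64
    return (2.0 * u - 1.0) * amplitude


def synthetic_oracle(smiles: str, params: Optional[OracleParams] = None) -> PropertyResult:
    """Deterministic toy ΔE_ST / E_S1 model; always returns status=ok."""
    p = params or OracleParams()
    can = canonicalize(smiles)
    feats = count_features(can)
    gap = (
        p.g0
        - p.w_sub * feats["substituents"]
        - p.w_n * feats["aromatic_N"]
        - p.w_amine * feats["diarylamine_N"]
        + _hash_noise(can, "gap", p.a_noise)
    )
    e_s1 = (
        p.s0
        - p.w_red * (feats["aromatic_N"] + feats["strong_donors"])
        + _hash_noise(can, "s1", p.a_noise)
    )
    return PropertyResult(
        smiles_canonical=can,
        gap=float(np.clip(gap, p.gap_min, p.gap_max)),
        e_s1=float(np.clip(e_s1, p.s_min, p.s_max)),
        status=ResultStatus.OK,
    )


class SyntheticOracle:
    """Engine adapter around :func:`synthetic_oracle` with fixed parameters."""

    def __init__(self, params: Optional[OracleParams] = None):
        self.params = params or OracleParams()

    def __call__(self, smiles: str) -> PropertyResult:
        return synthetic_oracle(smiles, self.params)


class TableEngine:
    """File-based stub engine replaying a property CSV.

    Expected columns: ``smiles, gap_eV, e_s1_eV, status``; molecules absent
    from the table are reported as geometry failures.
    """

    def __init__(self, path):
        df = pd.read_csv(path)
        self._table = {
            canonicalize(row.smiles): PropertyResult(
                canonicalize(row.smiles),
                gap=None if pd.isna(row.gap_eV) else float(row.gap_eV),
                e_s1=None if pd.isna(row.e_s1_eV) else float(row.e_s1_eV),
                status=ResultStatus(row.status),
            )
            for row in df.itertuples()
        }

    def __call__(self, smiles: str) -> PropertyResult:
        can = canonicalize(smiles)
        if can not in self._table:
            return PropertyResult(can, None, None, ResultStatus.GEOMETRY_FAILED)
        return self._table[can]


def evaluate_batch(
    molecules: Sequence[str],
    engine: Callable[[str], PropertyResult],
    policy: Optional[CompletenessPolicy] = None,
) -> List[PropertyResult]:
    """Run the engine per molecule and gate on batch completeness.

    Raises :class:`CompletenessError` if the geometry success fraction
    falls below ``geometry_min_ratio`` or the full-property success
    fraction below ``property_min_ratio``. Never drops molecules: the
    result list is index-aligned with the input (failures flagged).
    """
    if len(molecules) == 0:
        raise ValueError("evaluate_batch needs a non-empty molecule list")
    policy = policy or CompletenessPolicy()
    results = [engine(smi) for smi in molecules]
    n = len(results)
    geometry_ratio = sum(r.status is not ResultStatus.GEOMETRY_FAILED for r in results) / n
    property_ratio = sum(r.status is ResultStatus.OK for r in results) / n
    if geometry_ratio < policy.geometry_min_ratio or property_ratio < policy.property_min_ratio:
        raise CompletenessError(geometry_ratio, property_ratio, policy)
    return results


def write_property_csv(results: Iterable[PropertyResult], path) -> None:
    pd.DataFrame(
        [
            {
                "smiles": r.smiles_canonical,
                "gap_eV": r.gap,
                "e_s1_eV": r.e_s1,
                "status": r.status.value,
            }
            for r in results
        ]
    ).to_csv(path, index=False)


def kabsch_rmsd(coords_a, coords_b) -> float:
    """Minimal RMSD between two index-corresponding point sets.

    Both sets are centered and the optimal rigid rotation (Kabsch) of b
    onto a is applied, so the result is invariant to rigid motions of
    either input.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3 or b.ndim != 2 or b.shape[1] != 3:
        raise ValueError("coordinates must be (n, 3) arrays")
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"point-count mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] == 0:
        raise ValueError("need at least one point")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    if a.shape[0] == 1:
        return 0.0
    with warnings.catch_warnings():
        # collinear point sets leave the rotation underdetermined but the RMSD well-defined
        warnings.simplefilter("ignore", UserWarning)
        _, rssd = Rotation.align_vectors(a, b)
    return float(rssd / math.sqrt(a.shape[0]))


def load_xyz(path) -> np.ndarray:
    """Read coordinates from a plain XYZ file (element x y z per line)."""
    lines = Path(path).read_text().splitlines()
    try:
        n = int(lines[0].split()[0])
        body = lines[2 : 2 + n]
    except (ValueError, IndexError):
        body = [ln for ln in lines if len(ln.split()) == 4]
    return np.array([[float(x) for x in ln.split()[1:4]] for ln in body])
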
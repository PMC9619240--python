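"""The generational screening loop.

Each cycle on the current library G_n: a random 10% is evaluated by the
property engine, two fingerprint surrogates (gap and S1 energy) are fit on
that subset, the whole library is predicted, library metrics are reported
(material abundance, mean aromatic C-H count, mean gap, color sieve,
skeleton frequencies, similarity to the previous generation), molecules
with predicted gap below the optimality threshold are accumulated, and the
top 10% by predicted gap are mutated to form G_{n+1} (parents retained).
The loop stops at ``max_generations`` or when a convergence target on the
accumulated count or the abundance is met.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .chem import MoleculeRecord, mean_aromatic_ch, skeleton_frequencies
from .fragments import ConfigError, FragmentSet, Library, enumerate_da_library
from .mutate import MutationSpec, offspring_library
from .oracle import (
    CompletenessError,
    CompletenessPolicy,
    PropertyResult,
    ResultStatus,
    SyntheticOracle,
)
from .similarity import mspr_similarity
from .surrogate import SurrogateModel, featurize_library


@dataclass
class EvolutionConfig:
    """Run parameters; energies in eV, fractions in (0, 1]."""

    mutation: MutationSpec = field(default_factory=lambda: MutationSpec.from_label("Sub3"))
    library_cap: int = 1000
    train_fraction: float = 0.10
    select_fraction: float = 0.10
    optimal_gap_threshold: float = 0.15
    sieve_blue_min: float = 2.80
    sieve_red_max: float = 2.50
    max_generations: int = 9
    target_n_acc: Optional[int] = None
    target_abundance: Optional[float] = None
    criterion_logic: str = "any"
    geometry_min_ratio: float = 0.80
    property_min_ratio: float = 0.90
    seed: int = 0

    def validate(self) -> None:
        for name in ("train_fraction", "select_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if self.library_cap < 1:
            raise ConfigError(f"library_cap must be >= 1, got {self.library_cap}")
        if self.optimal_gap_threshold <= 0:
            raise ConfigError("optimal_gap_threshold must be positive")
        if not self.sieve_red_max < self.sieve_blue_min:
            raise ConfigError("sieve_red_max must be below sieve_blue_min")
        if self.max_generations < 0:
            raise ConfigError("max_generations must be >= 0")
        if self.criterion_logic not in ("any", "all"):
            raise ConfigError("criterion_logic must be 'any' or 'all'")
        if self.target_abundance is not None and not 0.0 < self.target_abundance <= 1.0:
            raise ConfigError("target_abundance must be in (0, 1]")
        if self.target_n_acc is not None and self.target_n_acc < 1:
            raise ConfigError("target_n_acc must be >= 1")
        for name in ("geometry_min_ratio", "property_min_ratio"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")


@dataclass
class GenerationReport:
    """Per-generation library metrics (one row of the trajectory table)."""

    n_g: int
    n_tot: int
    omega_ma: float
    n_ach_mean: float
    mean_gap: float
    n_acc_opt_mols: int
    sieve_blue: int
    sieve_green: int
    sieve_red: int
    n_inter: Optional[int] = None
    delta_mspr: Optional[float] = None
    skeleton_table_ref: str = ""


@dataclass
class EvolutionResult:
    reports: List[GenerationReport]
    accumulated: Dict[str, float]  # canonical SMILES -> predicted gap when first accumulated
    libraries: List[Library]
    skeleton_tables: Dict[str, pd.DataFrame]
    final_predictions: Dict[str, Tuple[float, float]]  # smiles -> (gap, e_s1)


def select_random_training(library: Library, fraction: float, seed: int) -> List[str]:
    """Seeded uniform sample of max(1, floor(fraction * n)) molecules."""
    if not 0.0 < fraction <= 1.0:
        raise ConfigError(f"fraction must be in (0, 1], got {fraction}")
    smiles = library.smiles()
    if not smiles:
        raise ConfigError("cannot sample a training set from an empty library")
    size = max(1, math.floor(fraction * len(smiles)))
    rng = np.random.default_rng(seed)
    return sorted(rng.choice(smiles, size=size, replace=False))


def select_top_fraction(predictions: Mapping[str, float], fraction: float) -> List[str]:
    """The max(1, floor(fraction * n)) molecules with smallest predicted gap.

    Ties are broken by canonical-SMILES lexicographic order; the result
    depends only on (predictions, fraction), not input ordering.
    """
    if not predictions:
        raise ConfigError("select_top_fraction over empty predictions")
    size = max(1, math.floor(fraction * len(predictions)))
    ranked = sorted(predictions.items(), key=lambda kv: (kv[1], kv[0]))
    return [smi for smi, _ in ranked[:size]]


def material_abundance(gaps: Sequence[float], threshold: float = 0.15) -> float:
    """Fraction of the library with predicted gap strictly below the threshold."""
    gaps = list(gaps)
    if not gaps:
        raise ConfigError("material_abundance over an empty gap list")
    return sum(g < threshold for g in gaps) / len(gaps)


def energy_sieve(
    e_s1_values: Mapping[str, float], blue_min: float = 2.80, red_max: float = 2.50
) -> Dict[str, str]:
    """Partition by vertical S1 energy: blue above ``blue_min``, red below
    ``red_max``, green in the closed interval between (boundaries are green)."""
    out = {}
    for smi, e in e_s1_values.items():
        if not math.isfinite(e):
            raise ValueError(f"non-finite E_S1 for {smi!r}")
        out[smi] = "blue" if e > blue_min else ("red" if e < red_max else "green")
    return out


def accumulate_optimal(
    accumulator: Set[str], library_gaps: Mapping[str, float], threshold: float = 0.15
) -> Set[str]:
    """Union of the accumulator with molecules whose predicted gap is below threshold."""
    return set(accumulator) | {s for s, g in library_gaps.items() if g < threshold}


def _substream_seeds(seed: int, n: int) -> List[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) % 2**31 for s in state]


def run_evolution(
    config: EvolutionConfig,
    fragments: FragmentSet,
    engine: Optional[Callable[[str], PropertyResult]] = None,
    compute_mspr: bool = True,
) -> EvolutionResult:
    """Execute the full selection-and-mutation loop; reproducible for a fixed seed.

    Returns one report per generation (G_0 included) plus the accumulated
    optimal set. Engine completeness failures abort with the generation
    index attached.
    """
    config.validate()
    engine = engine or SyntheticOracle()
    policy = CompletenessPolicy(config.geometry_min_ratio, config.property_min_ratio)
    seed_library, seed_train, seed_cap, seed_model = _substream_seeds(config.seed, 4)

    library = enumerate_da_library(fragments, cap=config.library_cap, seed=seed_library)
    reports: List[GenerationReport] = []
    libraries: List[Library] = []
    skeleton_tables: Dict[str, pd.DataFrame] = {}
    accumulated: Dict[str, float] = {}
    prev_smiles: Optional[List[str]] = None
    final_predictions: Dict[str, Tuple[float, float]] = {}

    for n_g in range(config.max_generations + 1):
        smiles = library.smiles()
        train = select_random_training(library, config.train_fraction, (seed_train + n_g) % 2**31)
        try:
            results = evaluate_generation(train, engine, policy)
        except CompletenessError as exc:
            raise CompletenessError(
                exc.geometry_ratio, exc.property_ratio, exc.policy, generation=n_g
            ) from exc

        ok = [r for r in results if r.status is ResultStatus.OK]
        features, _ = featurize_library([r.smiles_canonical for r in ok])
        gen_seed = (seed_model + n_g) % 2**31
        gap_model = SurrogateModel(target="gap", random_state=gen_seed).fit(
            features, [r.gap for r in ok]
        )
        s1_model = SurrogateModel(target="e_s1", random_state=gen_seed).fit(
            features, [r.e_s1 for r in ok]
        )
        lib_matrix, lib_keys = featurize_library(smiles)
        pred_gap = dict(zip(lib_keys, (float(v) for v in gap_model.predict(lib_matrix))))
        pred_s1 = dict(zip(lib_keys, (float(v) for v in s1_model.predict(lib_matrix))))

        omega = material_abundance(list(pred_gap.values()), config.optimal_gap_threshold)
        for smi, gap in pred_gap.items():
            if gap < config.optimal_gap_threshold and smi not in accumulated:
                accumulated[smi] = gap
        colors = energy_sieve(pred_s1, config.sieve_blue_min, config.sieve_red_max)
        counts = {c: 0 for c in ("blue", "green", "red")}
        for c in colors.values():
            counts[c] += 1

        ref = f"g{n_g}"
        skeleton_tables[f"{ref}_common"] = skeleton_frequencies(smiles, "common")
        skeleton_tables[f"{ref}_generic"] = skeleton_frequencies(smiles, "generic")

        n_inter = delta = None
        if prev_smiles is not None and compute_mspr:
            pairing = mspr_similarity(prev_smiles, smiles)
            n_inter, delta = pairing.n_inter, pairing.delta_mspr

        reports.append(
            GenerationReport(
                n_g=n_g,
                n_tot=len(smiles),
                omega_ma=omega,
                n_ach_mean=mean_aromatic_ch(smiles),
                mean_gap=float(np.mean(list(pred_gap.values()))),
                n_acc_opt_mols=len(accumulated),
                sieve_blue=counts["blue"],
                sieve_green=counts["green"],
                sieve_red=counts["red"],
                n_inter=n_inter,
                delta_mspr=delta,
                skeleton_table_ref=ref,
            )
        )
        libraries.append(library)
        final_predictions = {s: (pred_gap[s], pred_s1[s]) for s in smiles}

        if n_g == config.max_generations or _converged(config, len(accumulated), omega):
            break

        parents = select_top_fraction(pred_gap, config.select_fraction)
        parent_lib = Library(
            generation=n_g,
            records={s: library.records[s] for s in parents},
            cap=config.library_cap,
        )
        library = offspring_library(
            parent_lib, config.mutation, cap=config.library_cap, seed=(seed_cap + n_g) % 2**31
        )
        prev_smiles = smiles

    return EvolutionResult(
        reports=reports,
        accumulated=accumulated,
        libraries=libraries,
        skeleton_tables=skeleton_tables,
        final_predictions=final_predictions,
    )


def evaluate_generation(
    train: Sequence[str],
    engine: Callable[[str], PropertyResult],
    policy: CompletenessPolicy,
) -> List[PropertyResult]:
    from .oracle import evaluate_batch

    return evaluate_batch(train, engine, policy)


def _converged(config: EvolutionConfig, n_acc: int, omega: float) -> bool:
    checks = []
    if config.target_n_acc is not None:
        checks.append(n_acc >= config.target_n_acc)
    if config.target_abundance is not None:
        checks.append(omega >= config.target_abundance)
    if not checks:
        return False
    return any(checks) if config.criterion_logic == "any" else all(checks)


def trajectory_frame(reports: Sequence[GenerationReport]) -> pd.DataFrame:
    """Reports as a one-row-per-generation DataFrame (the trajectory table)."""
    return pd.DataFrame(
        [
            {
                "n_g": r.n_g,
                "n_tot": r.n_tot,
                "omega_ma": r.omega_ma,
                "n_ach_mean": r.n_ach_mean,
                "mean_gap": r.mean_gap,
                "n_acc_opt_mols": r.n_acc_opt_mols,
                "sieve_blue": r.sieve_blue,
                "sieve_green": r.sieve_green,
                "sieve_red": r.sieve_red,
                "n_inter": r.n_inter,
                "delta_mspr": r.delta_mspr,
                "skeleton_table_ref": r.skeleton_table_ref,
            }
            for r in reports
        ]
    )
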
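"""Run artifacts: final SAS ranking, trajectory serialization, config files.

The final screening product is the accumulated optimal set ranked by
synthetic accessibility (ascending: easiest to synthesize first), because
heavily mutated frameworks can drift into structures that are formally
optimal but practically unmakeable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .chem import sas_score
from .evolve import EvolutionConfig, GenerationReport, trajectory_frame
from .fragments import ConfigError
from .mutate import MutationSpec


@dataclass
class RankedCandidate:
    smiles_canonical: str
    predicted_gap: float
    sas: float
    rank: int
    sieve_color: Optional[str] = None


def rank_candidates(
    gaps: Mapping[str, float],
    top_k: Optional[int] = None,
    sieve_colors: Optional[Mapping[str, str]] = None,
    sas_fn=sas_score,
) -> List[RankedCandidate]:
    """Rank accumulated optimal molecules by ascending SAS.

    Ties break on ascending predicted gap, then lexicographic SMILES.
    ``top_k=None`` (or larger than the pool) returns everything.
    """
    if not gaps:
        raise ConfigError("rank_candidates needs a non-empty accumulator")
    scored = [(sas_fn(smi), gaps[smi], smi) for smi in gaps]
    scored.sort()
    if top_k is not None:
        scored = scored[:top_k]
    return [
        RankedCandidate(
            smiles_canonical=smi,
            predicted_gap=gap,
            sas=sas,
            rank=i + 1,
            sieve_color=sieve_colors.get(smi) if sieve_colors else None,
        )
        for i, (sas, gap, smi) in enumerate(scored)
    ]


def ranking_frame(candidates: Sequence[RankedCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": c.rank,
                "smiles": c.smiles_canonical,
                "sas": c.sas,
                "predicted_gap_eV": c.predicted_gap,
                "sieve_color": c.sieve_color,
            }
            for c in candidates
        ]
    )


def write_trajectory(reports: Sequence[GenerationReport], path) -> None:
    """One CSV row per generation; round-trips losslessly through read_trajectory."""
    if not reports:
        raise ValueError("write_trajectory needs at least one report")
    # 17 significant digits so every float survives the text roundtrip exactly
    trajectory_frame(reports).to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path) -> List[GenerationReport]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        n_inter = d["n_inter"]
        delta = d["delta_mspr"]
        out.append(
            GenerationReport(
                n_g=int(d["n_g"]),
                n_tot=int(d["n_tot"]),
                omega_ma=float(d["omega_ma"]),
                n_ach_mean=float(d["n_ach_mean"]),
                mean_gap=float(d["mean_gap"]),
                n_acc_opt_mols=int(d["n_acc_opt_mols"]),
                sieve_blue=int(d["sieve_blue"]),
                sieve_green=int(d["sieve_green"]),
                sieve_red=int(d["sieve_red"]),
                n_inter=None if pd.isna(n_inter) else int(n_inter),
                delta_mspr=None if (isinstance(delta, float) and math.isnan(delta)) else float(delta),
                skeleton_table_ref=str(d["skeleton_table_ref"]),
            )
        )
    return out


# Config file keys; energies carry an explicit _eV suffix in the file format.
_CONFIG_KEYS = {
    "mutation": ("mutation", lambda v: MutationSpec.from_label(str(v))),
    "library_cap": ("library_cap", int),
    "train_fraction": ("train_fraction", float),
    "select_fraction": ("select_fraction", float),
    "optimal_gap_threshold_eV": ("optimal_gap_threshold", float),
    "sieve_blue_min_eV": ("sieve_blue_min", float),
    "sieve_red_max_eV": ("sieve_red_max", float),
    "max_generations": ("max_generations", int),
    "target_n_acc": ("target_n_acc", int),
    "target_abundance": ("target_abundance", float),
    "criterion_logic": ("criterion_logic", str),
    "geometry_min_ratio": ("geometry_min_ratio", float),
    "property_min_ratio": ("property_min_ratio", float),
    "seed": ("seed", int),
}


def load_config(path) -> EvolutionConfig:
    """Read a flat YAML config; unknown keys are rejected, defaults applied."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file must hold a key-value mapping, got {type(data).__name__}")
    unknown = sorted(set(data) - set(_CONFIG_KEYS))
    if unknown:
        raise ConfigError(
            f"unknown config key(s): {', '.join(unknown)}; valid keys: {', '.join(_CONFIG_KEYS)}"
        )
    kwargs = {}
    for key, value in data.items():
        field_name, conv = _CONFIG_KEYS[key]
        if value is None:
            continue
        try:
            kwargs[field_name] = conv(value)
        except ConfigError:
            raise
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid value for {key!r}: {value!r} ({exc})")
    config = EvolutionConfig(**kwargs)
    config.validate()
    return config


def write_config(config: EvolutionConfig, path) -> None:
    """Snapshot a config in the flat file format (inverse of load_config)."""
    data = {
        "mutation": config.mutation.label,
        "library_cap": config.library_cap,
        "train_fraction": config.train_fraction,
        "select_fraction": config.select_fraction,
        "optimal_gap_threshold_eV": config.optimal_gap_threshold,
        "sieve_blue_min_eV": config.sieve_blue_min,
        "sieve_red_max_eV": config.sieve_red_max,
        "max_generations": config.max_generations,
        "target_n_acc": config.target_n_acc,
        "target_abundance": config.target_abundance,
        "criterion_logic": config.criterion_logic,
        "geometry_min_ratio": config.geometry_min_ratio,
        "property_min_ratio": config.property_min_ratio,
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
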
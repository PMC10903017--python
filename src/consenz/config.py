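"""YAML run configuration: per-section construction of policy objects.

Recognized sections::

    consensus:          # ConsensusPolicy fields
      tie_break: alphabetical
      polar_fallback: [N, Q]
      gap_rule: plurality-gap-deletes
      filler: A
      seed: 0
    symbols:            # SymbolMap overrides, symbol -> residue string
      "!": IV
    scoring:            # global-alignment scoring
      matrix: BLOSUM62
      gap_open: 10
      gap_extend: 0.5
    stoichiometry:      # compound -> molar mass (g/mol)
      L-Phe: 165.19
"""
from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .alignment_io import DEFAULT_SYMBOL_MAP, symbol_map_from_config
from .consensus_design import ConsensusPolicy
from .errors import InputError
from .pathway_quant import DEFAULT_MOLAR_MASSES, PathwayStoichiometry
from .sequence_comparison import ScoringParams


def load_config(path: str | Path | None) -> dict[str, Any]:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InputError(f"config {path} must be a mapping of sections")
    return cfg


def policy_from_config(cfg: dict[str, Any], seed: int | None = None) -> ConsensusPolicy:
    section = dict(cfg.get("consensus", {}))
    if "symbols" in cfg:
        section["symbol_map"] = symbol_map_from_config(
            {str(k): str(v) for k, v in cfg["symbols"].items()}
        )
    else:
        section.setdefault("symbol_map", dict(DEFAULT_SYMBOL_MAP))
    if "polar_fallback" in section:
        section["polar_fallback"] = tuple(section["polar_fallback"])
    if seed is not None:
        section["seed"] = seed
    return ConsensusPolicy(**section)


def scoring_from_config(cfg: dict[str, Any]) -> ScoringParams:
    return ScoringParams(**cfg.get("scoring", {}))


def stoichiometry_from_config(cfg: dict[str, Any]) -> PathwayStoichiometry:
    masses = dict(DEFAULT_MOLAR_MASSES)
    masses.update(cfg.get("stoichiometry", {}))
    return PathwayStoichiometry(molar_mass=masses)
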
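"""Rule-based consensus protein design from a multiple alignment.

The "wholesale" consensus procedure walks the alignment column by column and
chooses one residue (or a deletion) per column by frequency of appearance:

* the unique most frequent residue wins (plurality, not absolute majority);
* if the gap character is the unique plurality symbol the column is deleted
  from the design;
* if gaps occur but are outnumbered, the most frequent residue still wins
  ("gap rescue");
* residues tied for plurality are resolved either alphabetically
  (deterministic) or by a seeded random draw ("selected indiscriminately");
* a column with no plurality at all (every symbol unique) receives a small
  neutral filler: alanine when the ambiguity involves gaps, otherwise a
  polar, uncharged residue (asparagine, then glutamine) to keep the designed
  protein's charge neutral.

Each column's decision is recorded with its rule and counts so the final
design is fully auditable.
"""
from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .alignment_io import (
    AMINO_ACIDS,
    DEFAULT_SYMBOL_MAP,
    GAP,
    PROTEIN_ALPHABET,
    AlignedFamily,
    ProteinSequence,
    expand_symbol,
)
from .errors import BoundsError, InputError

TIE_BREAKS = ("alphabetical", "seeded-random")
GAP_RULES = ("plurality-gap-deletes", "majority-gap-deletes")


@dataclass(frozen=True)
class ConsensusPolicy:
    """Full rule set governing per-column residue choice.

    Parameters
    ----------
    tie_break
        ``alphabetical`` (deterministic) or ``seeded-random`` (draw among the
        tied residues with ``seed``).
    polar_fallback
        Preference order for fully-occupied columns with no plurality;
        default asparagine then glutamine.
    gap_rule
        ``plurality-gap-deletes``: the column is deleted when gap is the
        unique most frequent symbol.  ``majority-gap-deletes``: deletion
        additionally requires gaps in more than half the members.
    filler
        Residue used for gap-associated no-consensus columns (default A).
    symbol_map
        Consensus-class symbol expansion used when designing from a
        pre-computed consensus row.
    seed
        Seed for the ``seeded-random`` tie break.
    """

    tie_break: str = "alphabetical"
    polar_fallback: tuple[str, ...] = ("N", "Q")
    gap_rule: str = "plurality-gap-deletes"
    filler: str = "A"
    symbol_map: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_SYMBOL_MAP)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tie_break not in TIE_BREAKS:
            raise InputError(f"tie_break must be one of {TIE_BREAKS}")
        if self.gap_rule not in GAP_RULES:
            raise InputError(f"gap_rule must be one of {GAP_RULES}")
        if self.filler not in AMINO_ACIDS:
            raise InputError(f"filler {self.filler!r} is not a canonical residue")
        for r in self.polar_fallback:
            if r not in AMINO_ACIDS:
                raise InputError(f"polar_fallback residue {r!r} is not canonical")


@dataclass(frozen=True)
class ColumnDecision:
    """Outcome for one alignment column.

    ``column_index`` is 0-based internally; reports add 1 to match the
    residue-numbering convention used for positions like F397.
    """

    column_index: int
    action: str  # "residue" | "delete"
    residue: str | None
    rule_applied: str  # plurality | tie | polar_fallback | alanine_filler | gap_delete | gap_rescue
    counts: Mapping[str, int]


@dataclass(frozen=True)
class ConsensusResult:
    consensus: ProteinSequence
    decisions: tuple[ColumnDecision, ...]
    policy: ConsensusPolicy

    def decision_table(self) -> pd.DataFrame:
        """Per-column decision report with 1-based column numbers."""
        rows = []
        for d in self.decisions:
            rows.append(
                {
                    "column": d.column_index + 1,
                    "action": d.action,
                    "residue": d.residue or "",
                    "rule": d.rule_applied,
                    "counts": ";".join(
                        f"{sym}:{n}" for sym, n in sorted(d.counts.items())
                    ),
                }
            )
        return pd.DataFrame(rows, columns=["column", "action", "residue", "rule", "counts"])


def column_counts(family: AlignedFamily, index: int) -> dict[str, int]:
    """Count symbols (residues plus gap) in one alignment column."""
    col = family.column(index)  # raises BoundsError out of range
    return dict(Counter(col))


def _pick_tied(tied: list[str], policy: ConsensusPolicy, rng: random.Random | None) -> str:
    tied = sorted(tied)
    if policy.tie_break == "alphabetical" or len(tied) == 1:
        return tied[0]
    if rng is None:
        rng = random.Random(policy.seed)
    return rng.choice(tied)


def decide_column(
    counts: Mapping[str, int],
    policy: ConsensusPolicy | None = None,
    column_index: int = 0,
    rng: random.Random | None = None,
) -> ColumnDecision:
    """Apply the consensus rule set to one column's symbol counts."""
    if policy is None:
        policy = ConsensusPolicy()
    counts = dict(counts)
    total = sum(counts.values())
    if total <= 0:
        raise InputError("column counts sum to zero")
    for sym in counts:
        if sym != GAP and sym not in PROTEIN_ALPHABET:
            raise InputError(f"unknown symbol {sym!r} in column counts")

    gap_n = counts.get(GAP, 0)
    residue_counts = {r: n for r, n in counts.items() if r != GAP and n > 0}

    def _decision(action: str, residue: str | None, rule: str) -> ColumnDecision:
        return ColumnDecision(column_index, action, residue, rule, counts)

    if not residue_counts:
        return _decision("delete", None, "gap_delete")

    max_res = max(residue_counts.values())
    gap_wins = gap_n > max_res
    if policy.gap_rule == "majority-gap-deletes":
        gap_wins = gap_wins and gap_n * 2 > total
    if gap_wins:
        return _decision("delete", None, "gap_delete")

    top = [r for r, n in residue_counts.items() if n == max_res]
    if len(top) == 1:
        rule = "gap_rescue" if gap_n > 0 else "plurality"
        return _decision("residue", top[0], rule)

    if max_res > 1:
        return _decision("residue", _pick_tied(top, policy, rng), "tie")

    # Every symbol occurs exactly once: no consensus at all.
    if gap_n > 0:
        return _decision("residue", policy.filler, "alanine_filler")
    present = set(residue_counts)
    for preferred in policy.polar_fallback:
        if preferred in present:
            return _decision("residue", preferred, "polar_fallback")
    fallback = policy.polar_fallback[0] if policy.polar_fallback else policy.filler
    return _decision("residue", fallback, "polar_fallback")


def derive_consensus(
    family: AlignedFamily,
    policy: ConsensusPolicy | None = None,
    consensus_id: str = "consensus",
) -> ConsensusResult:
    """Derive the consensus protein for a family, column by column."""
    if policy is None:
        policy = ConsensusPolicy()
    rng = random.Random(policy.seed) if policy.tie_break == "seeded-random" else None
    decisions = []
    residues = []
    for i in range(family.length):
        try:
            d = decide_column(column_counts(family, i), policy, column_index=i, rng=rng)
        except InputError as exc:
            raise InputError(f"column {i + 1}: {exc}") from exc
        decisions.append(d)
        if d.action == "residue":
            residues.append(d.residue)
    if not residues:
        raise InputError("consensus is empty: every column was deleted")
    consensus = ProteinSequence(id=consensus_id, residues="".join(residues))
    return ConsensusResult(consensus=consensus, decisions=tuple(decisions), policy=policy)


def resolve_consensus_row(
    row: str,
    policy: ConsensusPolicy | None = None,
    consensus_id: str = "consensus",
) -> ProteinSequence:
    """Turn a pre-computed consensus line (MultAlin dialect) into a protein.

    Upper- and lower-case residue letters are taken as-is; class symbols are
    expanded through the policy's symbol map and resolved by the tie-break
    rule; gap or no-consensus marks (``-``, ``.``, `` ``) are dropped.
    Ambiguity codes B/Z inside an expansion resolve to N/Q respectively.
    """
    if policy is None:
        policy = ConsensusPolicy()
    rng = random.Random(policy.seed) if policy.tie_break == "seeded-random" else None
    ambiguity = {"B": "N", "Z": "Q"}
    out = []
    for ch in row:
        if ch in " .-~":
            continue
        residues = expand_symbol(ch, dict(policy.symbol_map))
        resolved = sorted(ambiguity.get(r, r) for r in residues)
        out.append(_pick_tied(resolved, policy, rng))
    if not out:
        raise InputError("consensus row contains no residues")
    return ProteinSequence(id=consensus_id, residues="".join(out))
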
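"""Stratification of homologs by percent identity to a query enzyme.

The design procedure builds two candidate families from one homolog search:
a high-identity tier (> 60% identity to the query) and a broader tier
(> 50%).  Identity is computed from a global pairwise alignment; the
denominator convention is explicit because reported percent identities
depend on it.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .alignment_io import GAP, ProteinSequence
from .errors import InputError
from .sequence_comparison import ScoringParams, global_align

IDENTITY_MODES = ("aligned-columns", "shorter-sequence")


@dataclass(frozen=True)
class IdentityReport:
    """Identity of every candidate to the query, plus the threshold applied."""

    query_id: str
    threshold: float
    pairs: tuple[tuple[str, float], ...]  # (member id, identity fraction)

    def as_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.pairs, columns=["id", "identity"])
        df["retained"] = df["identity"] > self.threshold
        return df


def pairwise_identity(
    a: ProteinSequence,
    b: ProteinSequence,
    mode: str = "aligned-columns",
    scoring: ScoringParams | None = None,
) -> float:
    """Fraction of identical residues between two proteins.

    ``aligned-columns``: matches / columns of the global alignment where
    neither symbol is a gap.  ``shorter-sequence``: matches / length of the
    shorter input, which penalizes length differences.
    """
    if mode not in IDENTITY_MODES:
        raise InputError(f"identity mode must be one of {IDENTITY_MODES}")
    if not a.residues or not b.residues:
        raise InputError("cannot compute identity of an empty sequence")
    pair = global_align(a, b, scoring)
    matches = 0
    cols = 0
    for x, y in zip(pair.a_gapped, pair.b_gapped):
        if x == GAP or y == GAP:
            continue
        cols += 1
        if x == y:
            matches += 1
    if mode == "aligned-columns":
        if cols == 0:
            return 0.0
        return matches / cols
    return matches / min(len(a), len(b))


def stratify_by_identity(
    query: ProteinSequence,
    candidates: Sequence[ProteinSequence],
    threshold: float,
    mode: str = "aligned-columns",
    scoring: ScoringParams | None = None,
) -> tuple[IdentityReport, list[ProteinSequence]]:
    """Retain candidates with identity to the query strictly above threshold.

    The report covers every candidate, retained or not; the retained subset
    preserves candidate order.  Threshold semantics are strictly greater
    than, matching "> 60%" / "> 50%" tier definitions.
    """
    if not 0.0 < threshold < 1.0:
        raise InputError(f"threshold must be in (0, 1), got {threshold}")
    pairs = []
    retained = []
    for cand in candidates:
        ident = pairwise_identity(query, cand, mode=mode, scoring=scoring)
        pairs.append((cand.id, ident))
        if ident > threshold:
            retained.append(cand)
    report = IdentityReport(query_id=query.id, threshold=threshold, pairs=tuple(pairs))
    return report, retained
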
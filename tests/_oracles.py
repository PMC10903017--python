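"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results by exhaustive enumeration or direct
counting, sharing no code with the package internals they check.
"""
from __future__ import annotations

from collections import Counter

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def oracle_consensus(rows: list[str]) -> str:
    """Frequency-rule consensus with alphabetical tie-break, by direct counting.

    Rules: gap as unique plurality deletes the column; otherwise the most
    frequent residue wins; residue ties (count >= 2) resolve alphabetically;
    all-singleton columns take alanine if gaps are present, else the first
    polar uncharged residue present in the column (N before Q), defaulting
    to N.
    """
    out = []
    for col in zip(*rows):
        counts = Counter(col)
        gap = counts.pop("-", 0)
        if not counts:
            continue
        top_count = max(counts.values())
        if gap > top_count:
            continue
        top = sorted(r for r, n in counts.items() if n == top_count)
        if len(top) == 1 or top_count > 1:
            out.append(top[0])
        elif gap > 0:
            out.append("A")
        elif "N" in counts:
            out.append("N")
        elif "Q" in counts:
            out.append("Q")
        else:
            out.append("N")
    return "".join(out)


def _affine_score(a_gapped: str, b_gapped: str, gap_open: float, gap_extend: float) -> float:
    """Score one explicit alignment under BLOSUM62 + affine gap runs."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(a_gapped, b_gapped):
        if x == "-":
            score -= gap_open if not in_gap_a else gap_extend
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score -= gap_open if not in_gap_b else gap_extend
            in_gap_a, in_gap_b = False, True
        else:
            score += _BLOSUM62[x, y]
            in_gap_a = in_gap_b = False
    return score


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment (no all-gap columns) of two strings."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ga, gb in enumerate_alignments(a[1:], b):
            yield a[0] + ga, "-" + gb
    if b:
        for ga, gb in enumerate_alignments(a, b[1:]):
            yield "-" + ga, b[0] + gb
    if a and b:
        for ga, gb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ga, b[0] + gb


def oracle_best_alignment_score(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> float:
    """Optimal global alignment score by exhaustive enumeration."""
    return max(
        _affine_score(ga, gb, gap_open, gap_extend)
        for ga, gb in enumerate_alignments(a, b)
    )


def oracle_ols_slope(times: list[float], concs: list[float]) -> float:
    """Closed-form OLS slope."""
    n = len(times)
    mt = sum(times) / n
    mc = sum(concs) / n
    num = sum((t - mt) * (c - mc) for t, c in zip(times, concs))
    den = sum((t - mt) ** 2 for t in times)
    return num / den
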
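"""Protein sequence and multiple-alignment I/O.

Reads and writes plain FASTA, aligned FASTA and Clustal-style alignments via
Biopython, plus the MultAlin dialect in which the final row of each block is a
consensus line that may contain conservation-class symbols (``!``, ``$``,
``%``, ``#``) instead of residues.  Class symbols are expanded through a
:class:`SymbolMap`; the default map follows the MultAlin convention and can be
overridden from a config file.
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentFormatError, AlphabetError, SymbolError

logger = logging.getLogger(__name__)

#: The twenty canonical amino-acid one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Canonical alphabet plus X (unknown residue).
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS) | {"X"}
#: Canonical gap character; '.' and '~' are normalized to this on input.
GAP = "-"
_ALT_GAPS = ".~"

#: Default consensus-class symbol map (MultAlin convention).  ``#`` includes
#: the ambiguity codes B (N/D) and Z (Q/E) alongside the residues they stand
#: for.  Fully overridable via :func:`symbol_map_from_config`.
DEFAULT_SYMBOL_MAP: dict[str, frozenset[str]] = {
    "!": frozenset("IV"),
    "$": frozenset("LM"),
    "%": frozenset("FY"),
    "#": frozenset("NDQEBZ"),
}


@dataclass(frozen=True)
class ProteinSequence:
    """An ungapped protein sequence over the canonical alphabet (plus X)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlphabetError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(self.residues):
            if ch not in PROTEIN_ALPHABET:
                raise AlphabetError(
                    f"sequence {self.id!r}: illegal character {ch!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GappedSequence:
    """One row of a multiple alignment: residues plus ``-`` gap characters."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlphabetError(f"aligned sequence {self.id!r} is empty")
        for pos, ch in enumerate(self.residues):
            if ch != GAP and ch not in PROTEIN_ALPHABET:
                raise AlphabetError(
                    f"aligned sequence {self.id!r}: illegal character {ch!r} "
                    f"at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def degap(self) -> ProteinSequence:
        """Strip gaps, returning the underlying protein sequence."""
        return ProteinSequence(
            id=self.id,
            residues=self.residues.replace(GAP, ""),
            description=self.description,
        )

    @property
    def gap_count(self) -> int:
        return self.residues.count(GAP)


@dataclass(frozen=True)
class AlignedFamily:
    """A protein multiple alignment: equal-length gapped member sequences.

    ``consensus_row`` carries a pre-computed consensus line (possibly with
    class symbols) when the source was a MultAlin-style file; it is not a
    member of the alignment.
    """

    members: tuple[GappedSequence, ...]
    query_id: str | None = None
    source_format: str = "aligned-fasta"
    consensus_row: str | None = None

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise AlignmentFormatError(
                f"alignment needs >= 2 members, got {len(self.members)}"
            )
        lengths = {len(m) for m in self.members}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"unequal alignment row lengths: {sorted(lengths)}"
            )
        if self.consensus_row is not None and len(self.consensus_row) != self.length:
            raise AlignmentFormatError(
                "consensus row length does not match alignment length"
            )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.members[0])

    @property
    def size(self) -> int:
        """Number of member sequences."""
        return len(self.members)

    def column(self, index: int) -> str:
        """Column ``index`` (0-based) as a string, one symbol per member."""
        from .errors import BoundsError

        if not 0 <= index < self.length:
            raise BoundsError(
                f"column {index} out of range for alignment of length {self.length}"
            )
        return "".join(m.residues[index] for m in self.members)

    def member(self, seq_id: str) -> GappedSequence:
        for m in self.members:
            if m.id == seq_id:
                return m
        raise KeyError(seq_id)


def _normalize_gaps(seq: str) -> str:
    for alt in _ALT_GAPS:
        seq = seq.replace(alt, GAP)
    return seq


def _dedupe_ids(records: Iterable[tuple[str, str, str]]) -> list[tuple[str, str, str]]:
    seen: dict[str, int] = {}
    out = []
    for sid, seq, desc in records:
        if sid in seen:
            seen[sid] += 1
            new_id = f"{sid}.{seen[sid]}"
            logger.warning("duplicate sequence id %r renamed to %r", sid, new_id)
            sid = new_id
        else:
            seen[sid] = 0
        out.append((sid, seq, desc))
    return out


def _strip_id_from_description(record: SeqRecord) -> str:
    desc = record.description or ""
    if desc.startswith(record.id):
        desc = desc[len(record.id):].strip()
    return desc


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read unaligned protein sequences from a FASTA file."""
    records = [
        (r.id, _normalize_gaps(str(r.seq)).replace(GAP, ""), _strip_id_from_description(r))
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise AlignmentFormatError(f"no sequences found in {path}")
    return [ProteinSequence(sid, seq, desc) for sid, seq, desc in _dedupe_ids(records)]


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            header = f">{s.id} {s.description}".rstrip()
            fh.write(f"{header}\n{s.residues}\n")


def _parse_multalin(path: str | Path) -> tuple[list[tuple[str, str, str]], str | None]:
    """Parse a MultAlin-style block alignment.

    Blocks are separated by blank lines; each line is ``name  segment``.  A row
    named ``Consensus`` (case-insensitive) is pulled out and returned
    separately, raw (class symbols preserved, no gap normalization).
    """
    order: list[str] = []
    chunks: dict[str, list[str]] = {}
    consensus_parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith(("//", "#")):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                continue
            name, segment = parts
            segment = segment.replace(" ", "")
            if name.lower() == "consensus":
                consensus_parts.append(segment)
                continue
            if name not in chunks:
                order.append(name)
                chunks[name] = []
            chunks[name].append(segment)
    rows = [(name, "".join(chunks[name]), "") for name in order]
    consensus = "".join(consensus_parts) or None
    return rows, consensus


def read_alignment(path: str | Path, format: str = "aligned-fasta") -> AlignedFamily:
    """Read a protein multiple alignment.

    Parameters
    ----------
    path
        Input file.
    format
        ``aligned-fasta``, ``clustal`` or ``multalin``.  Clustal conservation
        lines are discarded by the parser; MultAlin ``Consensus`` rows are
        kept on ``AlignedFamily.consensus_row``.
    """
    consensus_row: str | None = None
    if format == "aligned-fasta":
        rows = [
            (r.id, str(r.seq), _strip_id_from_description(r))
            for r in SeqIO.parse(str(path), "fasta")
        ]
    elif format == "clustal":
        try:
            aln = AlignIO.read(str(path), "clustal")
        except ValueError as exc:
            raise AlignmentFormatError(f"cannot parse {path} as clustal: {exc}") from exc
        rows = [(r.id, str(r.seq), _strip_id_from_description(r)) for r in aln]
    elif format == "multalin":
        rows, consensus_row = _parse_multalin(path)
    else:
        raise AlignmentFormatError(f"unknown alignment format {format!r}")

    if not rows:
        raise AlignmentFormatError(f"no sequences found in {path}")
    rows = [(sid, _normalize_gaps(seq).upper(), desc) for sid, seq, desc in rows]
    lengths = {len(seq) for _, seq, _ in rows}
    if len(lengths) != 1:
        raise AlignmentFormatError(
            f"{path}: unequal alignment row lengths {sorted(lengths)}"
        )
    members = tuple(
        GappedSequence(sid, seq, desc) for sid, seq, desc in _dedupe_ids(rows)
    )
    return AlignedFamily(
        members=members, source_format=format, consensus_row=consensus_row
    )


def write_alignment(family: AlignedFamily, path: str | Path, format: str = "aligned-fasta") -> None:
    """Write an alignment; member order is preserved."""
    if format == "aligned-fasta":
        with open(path, "w") as fh:
            for m in family.members:
                header = f">{m.id} {m.description}".rstrip()
                fh.write(f"{header}\n{m.residues}\n")
    elif format == "clustal":
        aln = MultipleSeqAlignment(
            SeqRecord(Seq(m.residues), id=m.id, description=m.description)
            for m in family.members
        )
        AlignIO.write(aln, str(path), "clustal")
    else:
        raise AlignmentFormatError(f"unknown alignment format {format!r}")


def expand_symbol(symbol: str, symbol_map: dict[str, frozenset[str]] | None = None) -> frozenset[str]:
    """Expand one consensus-line symbol to the set of residues it denotes.

    A canonical residue expands to its own singleton set; a class symbol is
    looked up in ``symbol_map`` (default: MultAlin convention).
    """
    if symbol_map is None:
        symbol_map = DEFAULT_SYMBOL_MAP
    up = symbol.upper()
    if up in PROTEIN_ALPHABET:
        return frozenset({up})
    if symbol in symbol_map:
        return frozenset(symbol_map[symbol])
    raise SymbolError(f"unknown consensus symbol {symbol!r}")


def symbol_map_from_config(section: dict[str, str]) -> dict[str, frozenset[str]]:
    """Build a SymbolMap from a config section mapping symbol -> residue string.

    Example section: ``{"!": "IV", "$": "LM"}``.  Symbols must not collide with
    the amino-acid alphabet and residue sets must be non-empty.
    """
    out: dict[str, frozenset[str]] = {}
    for symbol, residues in section.items():
        if symbol.upper() in PROTEIN_ALPHABET:
            raise SymbolError(f"symbol {symbol!r} collides with the amino-acid alphabet")
        rset = frozenset(residues.upper())
        if not rset:
            raise SymbolError(f"symbol {symbol!r} maps to an empty residue set")
        out[symbol] = rset
    return out
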
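"""Back-translation of a designed protein into a host-optimized CDS.

Two transparent codon-choice modes are provided: ``max-frequency`` (always
the host's most used synonymous codon; deterministic) and
``weighted-sampled`` (codons drawn with the host's usage frequencies under a
seed; reproducible).  Designed genes destined for cloning between BamHI and
EcoRI sites must not contain those recognition motifs internally, on either
strand; conflicts are resolved by the lowest-cost synonymous substitution
covering the motif.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq

from .alignment_io import AMINO_ACIDS, ProteinSequence
from .errors import DesignInfeasibleError, InputError, PrematureStopError

#: BamHI and EcoRI recognition sites; the designed gene is cloned between
#: these, so they must not occur inside the CDS.
DEFAULT_FORBIDDEN_MOTIFS = ("GGATCC", "GAATTC")
#: 5'/3' flanks applied when a clonable fragment is requested.
DEFAULT_FLANKS = ("GGATCC", "GAATTC")

BACKTRANSLATE_MODES = ("max-frequency", "weighted-sampled")

_STANDARD = _BioCodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid for the 61 sense codons of the standard code.
GENETIC_CODE: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-organism synonymous codon usage.

    ``usage`` maps each DNA codon to its relative frequency *within its
    amino-acid family* (fractions per family sum to 1); stop codons are
    carried the same way under ``stop_usage``.
    """

    organism: str
    usage: Mapping[str, float]
    stop_usage: Mapping[str, float]

    def __post_init__(self) -> None:
        sense = set(GENETIC_CODE)
        missing = sense - set(self.usage)
        if missing:
            raise InputError(f"codon table missing {len(missing)} sense codons: "
                             f"{sorted(missing)[:5]}...")
        by_aa: dict[str, float] = {}
        for codon, freq in self.usage.items():
            if codon not in sense:
                raise InputError(f"{codon!r} is not a sense codon")
            if freq < 0:
                raise InputError(f"negative frequency for {codon}")
            by_aa[GENETIC_CODE[codon]] = by_aa.get(GENETIC_CODE[codon], 0.0) + freq
        for aa, total in by_aa.items():
            if abs(total - 1.0) > 1e-6:
                raise InputError(
                    f"frequencies for amino acid {aa} sum to {total}, not 1"
                )
        if not self.stop_usage:
            raise InputError("codon table has no stop codons")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(self.stop_usage)

    def codons_for(self, aa: str) -> list[str]:
        """Synonymous codons for ``aa``, most frequent first (ties alphabetical)."""
        cands = [c for c, a in GENETIC_CODE.items() if a == aa]
        if not cands:
            raise InputError(f"no codons for amino acid {aa!r}")
        return sorted(cands, key=lambda c: (-self.usage[c], c))

    def max_codon(self, aa: str) -> str:
        return self.codons_for(aa)[0]

    def sample_codon(self, aa: str, rng: np.random.Generator) -> str:
        cands = sorted(c for c, a in GENETIC_CODE.items() if a == aa)
        weights = np.array([self.usage[c] for c in cands], dtype=float)
        weights = weights / weights.sum()
        return cands[int(rng.choice(len(cands), p=weights))]

    def preferred_stop(self) -> str:
        return max(sorted(self.stop_usage), key=lambda c: self.stop_usage[c])

    @classmethod
    def from_tsv(cls, path: str | Path, organism: str | None = None) -> "CodonUsageTable":
        """Load a table from TSV columns (codon, amino_acid, fraction)."""
        usage: dict[str, float] = {}
        stops: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                codon, aa, frac = line.split("\t")
                codon = codon.upper().replace("U", "T")
                if aa == "*":
                    stops[codon] = float(frac)
                else:
                    usage[codon] = float(frac)
        return cls(organism=organism or Path(path).stem, usage=usage, stop_usage=stops)


def load_default_table() -> CodonUsageTable:
    """The bundled Pseudomonas putida codon-usage table."""
    ref = importlib.resources.files("consenz") / "data" / "codon_usage_p_putida.tsv"
    with importlib.resources.as_file(ref) as path:
        return CodonUsageTable.from_tsv(path, organism="Pseudomonas putida")


@dataclass(frozen=True)
class DesignedGene:
    """A codon-optimized CDS tied to its source protein.

    ``cds`` includes exactly one trailing stop codon; ``flanks``, when set,
    are the restriction-site sequences added outside the CDS for cloning.
    """

    protein_id: str
    cds: str
    mode: str
    seed: int | None = None
    forbidden_motifs: tuple[str, ...] = DEFAULT_FORBIDDEN_MOTIFS
    flanks: tuple[str, str] | None = None

    @property
    def fragment(self) -> str:
        """CDS with cloning flanks applied (equals ``cds`` if no flanks)."""
        if self.flanks is None:
            return self.cds
        return self.flanks[0] + self.cds + self.flanks[1]


def translate(cds: str) -> ProteinSequence:
    """Standard-code translation of a CDS; the trailing stop is removed.

    Raises :class:`PrematureStopError` (with the 0-based codon index) on an
    internal stop codon.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise InputError(f"CDS length {len(cds)} is not a multiple of 3")
    if set(cds) - set("ACGT"):
        raise InputError("CDS contains non-ACGT characters")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    residues = []
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise PrematureStopError(f"internal stop codon {codon} at codon index {i}")
        residues.append(GENETIC_CODE[codon])
    if not residues:
        raise InputError("CDS encodes no residues")
    return ProteinSequence(id="translated", residues="".join(residues))


def scan_motifs(cds: str, motifs: Iterable[str]) -> list[tuple[str, str, int]]:
    """All occurrences of each motif on both strands.

    Returns ``(motif, strand, start)`` with ``start`` the 0-based position of
    the occurrence's span on the forward strand.  A palindromic site appears
    once per strand at the same span.
    """
    cds = cds.upper()
    hits: list[tuple[str, str, int]] = []
    for motif in motifs:
        motif = motif.upper()
        if set(motif) - set("ACGT"):
            raise InputError(f"motif {motif!r} contains non-ACGT characters")
        start = cds.find(motif)
        while start != -1:
            hits.append((motif, "+", start))
            start = cds.find(motif, start + 1)
        rc = reverse_complement(cds)
        start = rc.find(motif)
        while start != -1:
            hits.append((motif, "-", len(cds) - start - len(motif)))
            start = rc.find(motif, start + 1)
    return sorted(hits, key=lambda h: (h[2], h[1], h[0]))


def _initial_codons(
    protein: ProteinSequence,
    table: CodonUsageTable,
    mode: str,
    rng: np.random.Generator | None,
) -> list[str]:
    if mode == "max-frequency":
        return [table.max_codon(aa) for aa in protein.residues]
    assert rng is not None
    return [table.sample_codon(aa, rng) for aa in protein.residues]


def _resolve_motifs(
    codons: list[str],
    table: CodonUsageTable,
    motifs: Sequence[str],
) -> list[str]:
    """Remove forbidden motifs by lowest-cost synonymous substitutions.

    For each motif hit, every codon overlapping the hit span is considered;
    candidate synonymous replacements are ranked by usage-frequency loss and
    the first one that clears the hit without raising the total hit count is
    applied.  Raises :class:`DesignInfeasibleError` if no substitution works.
    """
    max_rounds = 4 * len(codons) + 16
    for _ in range(max_rounds):
        cds = "".join(codons)
        hits = scan_motifs(cds, motifs)
        if not hits:
            return codons
        motif, _, start = hits[0]
        end = start + len(motif)
        first_codon = start // 3
        last_codon = (end - 1) // 3
        candidates: list[tuple[float, int, str]] = []
        for ci in range(first_codon, last_codon + 1):
            current = codons[ci]
            aa = GENETIC_CODE[current] if current in GENETIC_CODE else "*"
            if aa == "*":
                syns = sorted(table.stop_usage, key=lambda c: (-table.stop_usage[c], c))
                freq = table.stop_usage
            else:
                syns = table.codons_for(aa)
                freq = table.usage
            for alt in syns:
                if alt == current:
                    continue
                candidates.append((freq[current] - freq[alt], ci, alt))
        candidates.sort(key=lambda t: (t[0], t[1], t[2]))
        n_before = len(hits)
        for _cost, ci, alt in candidates:
            trial = list(codons)
            trial[ci] = alt
            trial_hits = scan_motifs("".join(trial), motifs)
            span_clear = all(
                not (h_start < end and h_start + len(h_motif) > start)
                for h_motif, _s, h_start in trial_hits
            )
            if span_clear and len(trial_hits) < n_before:
                codons = trial
                break
        else:
            raise DesignInfeasibleError(
                f"cannot remove motif {motif} at position {start}: "
                "no synonymous substitution clears it"
            )
    raise DesignInfeasibleError("motif resolution did not converge")


def back_translate(
    protein: ProteinSequence,
    table: CodonUsageTable | None = None,
    mode: str = "max-frequency",
    seed: int | None = None,
    forbidden_motifs: Sequence[str] = DEFAULT_FORBIDDEN_MOTIFS,
    add_flanks: bool = False,
) -> DesignedGene:
    """Design a host-optimized CDS (with one stop codon) for a protein.

    The returned CDS translates back to ``protein`` exactly and contains no
    forbidden motif on either strand.  ``add_flanks`` wraps the CDS with
    BamHI/EcoRI sites for cloning (outside the CDS itself).
    """
    if table is None:
        table = load_default_table()
    if mode not in BACKTRANSLATE_MODES:
        raise InputError(f"mode must be one of {BACKTRANSLATE_MODES}")
    if "X" in protein.residues:
        raise InputError(
            f"protein {protein.id!r} contains X; back-translation needs "
            "fully specified residues"
        )
    rng = np.random.default_rng(seed) if mode == "weighted-sampled" else None
    codons = _initial_codons(protein, table, mode, rng)
    codons.append(table.preferred_stop())
    motifs = tuple(m.upper() for m in forbidden_motifs)
    if motifs:
        codons = _resolve_motifs(codons, table, motifs)
    cds = "".join(codons)
    # paranoia: the design must survive its own invariants
    assert translate(cds).residues == protein.residues
    return DesignedGene(
        protein_id=protein.id,
        cds=cds,
        mode=mode,
        seed=seed,
        forbidden_motifs=motifs,
        flanks=DEFAULT_FLANKS if add_flanks else None,
    )
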
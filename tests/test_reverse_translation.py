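import random

import numpy as np
import pytest

from consenz.alignment_io import AMINO_ACIDS, ProteinSequence
from consenz.errors import (
    DesignInfeasibleError,
    InputError,
    PrematureStopError,
)
from consenz.reverse_translation import (
    GENETIC_CODE,
    CodonUsageTable,
    back_translate,
    reverse_complement,
    scan_motifs,
    translate,
)


def protein(s, sid="p"):
    return ProteinSequence(sid, s)


# -- codon table ------------------------------------------------------------

def test_bundled_table_covers_61_sense_codons(codon_table):
    assert set(codon_table.usage) == set(GENETIC_CODE)
    assert codon_table.stop_codons == {"TAA", "TAG", "TGA"}


def test_table_rejects_bad_frequency_sums():
    usage = {c: (1.0 if c == sorted(cs)[0] else 0.0)
             for aa in set(GENETIC_CODE.values())
             for cs in [[c for c, a in GENETIC_CODE.items() if a == aa]]
             for c in cs}
    usage["GCC"] = 0.5  # alanine family no longer sums to 1
    with pytest.raises(InputError, match="sum"):
        CodonUsageTable("broken", usage, {"TAA": 1.0})


# -- translate --------------------------------------------------------------

def test_translate_single_codon_with_stop():
    assert translate("ATGTAA").residues == "M"


def test_translate_internal_stop_raises_with_index():
    with pytest.raises(PrematureStopError, match="index 1"):
        translate("ATGTGATAA")


def test_translate_rejects_partial_codons():
    with pytest.raises(InputError):
        translate("ATGTA")


# -- scan_motifs ------------------------------------------------------------

def test_scan_finds_forward_hit():
    assert scan_motifs("AAGGATCCTT", ["GGATCC"]) == [
        ("GGATCC", "+", 2), ("GGATCC", "-", 2)
    ]


def test_scan_absent_motif_empty():
    assert scan_motifs("ATGATGATG", ["GAATTC"]) == []


def test_scan_palindrome_reported_once_per_strand_same_span():
    hits = scan_motifs("TTGAATTCAA", ["GAATTC"])
    spans = {(s, start) for _, s, start in hits}
    assert spans == {("+", 2), ("-", 2)}


def test_scan_non_palindromic_motif_on_reverse_strand():
    motif = "GGGTTA"
    cds = "CC" + reverse_complement(motif) + "CC"
    hits = scan_motifs(cds, [motif])
    assert hits == [(motif, "-", 2)]


# -- back_translate ---------------------------------------------------------

def test_single_methionine_gene(codon_table):
    gene = back_translate(protein("M"), codon_table)
    assert len(gene.cds) == 6
    assert gene.cds.startswith("ATG")
    assert gene.cds[3:] in codon_table.stop_codons


def test_cds_length_is_three_times_length_plus_stop(codon_table):
    p = protein("".join(random.Random(0).choices(AMINO_ACIDS, k=502)))
    gene = back_translate(p, codon_table)
    assert len(gene.cds) == 3 * (502 + 1) == 1509


def test_round_trip_both_modes(codon_table):
    rng = random.Random(123)
    for mode in ("max-frequency", "weighted-sampled"):
        for _ in range(25):
            p = protein("".join(rng.choices(AMINO_ACIDS, k=rng.randint(1, 120))))
            gene = back_translate(p, codon_table, mode=mode, seed=9)
            assert translate(gene.cds).residues == p.residues
            assert scan_motifs(gene.cds, gene.forbidden_motifs) == []


def test_max_frequency_mode_deterministic(codon_table):
    p = protein("MKTAYIAKQRQISFVKSHFSRQ")
    assert back_translate(p, codon_table).cds == back_translate(p, codon_table).cds


def test_weighted_mode_seed_reproducible_and_seed_sensitive(codon_table):
    p = protein("".join(random.Random(5).choices(AMINO_ACIDS, k=80)))
    g1 = back_translate(p, codon_table, mode="weighted-sampled", seed=1)
    g2 = back_translate(p, codon_table, mode="weighted-sampled", seed=1)
    g3 = back_translate(p, codon_table, mode="weighted-sampled", seed=2)
    assert g1.cds == g2.cds
    assert g1.cds != g3.cds


def test_codon_frequencies_match_table_in_sampled_mode(codon_table):
    # leucine has six codons; sampled proportions should track the table
    p = protein("L" * 4000)
    gene = back_translate(p, codon_table, mode="weighted-sampled", seed=0,
                          forbidden_motifs=())
    codons = [gene.cds[i:i + 3] for i in range(0, len(gene.cds) - 3, 3)]
    for codon in ("CTG", "CTC", "TTA"):
        observed = codons.count(codon) / len(codons)
        expected = codon_table.usage[codon]
        se = np.sqrt(expected * (1 - expected) / len(codons))
        assert abs(observed - expected) < 5 * se


def test_motif_conflict_resolved_by_synonymous_swap():
    # A table whose max-frequency codons for G and S spell out GGATCC
    usage = {}
    for aa in set(GENETIC_CODE.values()):
        codons = sorted(c for c, a in GENETIC_CODE.items() if a == aa)
        pref = {"G": "GGA", "S": "TCC"}.get(aa, codons[0])
        for c in codons:
            usage[c] = 1.0 if c == pref else 0.0
    usage = {c: (f if f else 0.0) for c, f in usage.items()}
    # spread tiny mass so every codon family still sums to 1 exactly
    table = CodonUsageTable("adversarial", _renorm(usage), {"TAA": 1.0})
    gene = back_translate(protein("GS"), table, forbidden_motifs=("GGATCC",))
    assert "GGATCC" not in gene.cds
    assert "GGATCC" not in reverse_complement(gene.cds)
    assert translate(gene.cds).residues == "GS"


def _renorm(usage):
    from collections import defaultdict
    totals = defaultdict(float)
    counts = defaultdict(int)
    for c in usage:
        counts[GENETIC_CODE[c]] += 1
    out = {}
    for c, f in usage.items():
        aa = GENETIC_CODE[c]
        # 0.9 to the preferred codon, remainder spread over the others
        n = counts[aa]
        if n == 1:
            out[c] = 1.0
        elif f == 1.0:
            out[c] = 0.9
        else:
            out[c] = 0.1 / (n - 1)
    return out


def test_x_residue_rejected(codon_table):
    with pytest.raises(InputError, match="X"):
        back_translate(protein("MXK"), codon_table)


def test_unavoidable_motif_is_design_infeasible(codon_table):
    # forbidding ATG makes any methionine impossible (single codon)
    with pytest.raises(DesignInfeasibleError):
        back_translate(protein("KMK"), codon_table, forbidden_motifs=("ATG",))


def test_flanks_wrap_cds_once(codon_table):
    gene = back_translate(protein("MKTAY"), codon_table, add_flanks=True)
    frag = gene.fragment
    assert frag.startswith("GGATCC") and frag.endswith("GAATTC")
    assert frag.count("GGATCC") == 1
    assert gene.cds == frag[6:-6]
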
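# Methods

## The consensus ("wholesale") design procedure

The design operates on a protein multiple alignment and is purely
frequency-based: no phylogenetic weighting, no structural information.
Per column, with residue counts `c_r` and gap count `g` over `n` members:

1. **Gap deletion.** If the gap is the unique plurality symbol
   (`g > max_r c_r`), the column is deleted — an absent residue in most
   homologs is treated as an absent residue in the design. A stricter
   variant (`gap_rule: majority-gap-deletes`) additionally requires
   `g > n/2`.
2. **Plurality.** Otherwise the unique most frequent residue is chosen.
   When gaps are present but outnumbered the rule is recorded as
   `gap_rescue` rather than `plurality`, so the decision log distinguishes
   fully occupied columns from rescued ones.
3. **Ties.** Two or more residues tied at the top (count ≥ 2) are resolved
   either alphabetically (default — deterministic and reproducible) or by
   a seeded random draw among the tied set, matching the idea of picking
   either tied residue indiscriminately. Both modes are first-class; the
   seed is part of the policy and recorded with the result.
4. **No consensus.** If every symbol in the column is unique there is no
   frequency signal at all. With gaps involved the design takes the filler
   residue (default alanine: small, neutral, minimally perturbing to
   folding). In fully occupied columns it takes a polar uncharged residue
   to keep net charge neutral — the first of the preference list (N, then
   Q) present in the column, defaulting to N when neither occurs.

The rule precedence (gap deletion → plurality → tie → filler/polar) is a
design choice: the two fallbacks are stated independently in the
literature on this procedure without an explicit decision tree, and this
ordering is the one under which each fallback applies exactly in its
stated context (alanine only where gaps created the ambiguity, polar
fallback only in fully occupied columns).

Every column yields a `ColumnDecision` (action, residue, rule, counts),
so `consensus length = alignment length − gap-deleted columns` is
auditable per design. Column indices are 0-based internally and 1-based in
all user-facing tables, matching residue-numbering conventions like F397.

Pre-computed consensus rows (MultAlin dialect) may carry conservation-class
symbols instead of residues; the default symbol map is the MultAlin
convention (`!` = I/V, `$` = L/M, `%` = F/Y, `#` = N/D/Q/E/B/Z) and is
fully overridable from the config file, since published symbol tables vary.
Ambiguity codes B/Z resolve to N/Q.

## Percent identity and stratification

Identity is computed from a global alignment (below), as
`matches / aligned columns` (gap-excluded denominator, the default) or
`matches / min(len a, len b)`. The gap-excluded convention approximates
what BLAST-style searches report and is therefore the default for
reproducing identity tiers quoted from database searches; the alternative
is exposed because the choice changes values for length-mismatched pairs.
Tier membership uses strictly-greater-than semantics (`> 60%`, `> 50%`).

## Global alignment, differences, key residues

Alignment is Needleman–Wunsch with affine gaps via Biopython's
`PairwiseAligner`: BLOSUM62, gap open 10, gap extend 0.5 (a gap of length
L costs `open + (L−1)·extend`). All parameters are configurable. Among
co-optimal alignments the aligner's first traceback is used; it is
deterministic for fixed inputs and scoring, which is what downstream
reports need. Score-level optimality is cross-checked in the test suite
against exhaustive enumeration of all alignments for short sequences.

Residue differences are counted as mismatched columns plus one per gap
column. This is stated prominently because published difference counts
rarely define their convention, and it is the only reading that is
consistent when the two sequences differ in length. Because such counts
are sensitive to gap penalties, `difference_count_grid` re-computes the
count over a small penalty grid (open ∈ {8, 10, 12} × extend ∈ {0.5, 1,
2} by default) so a report can document which parameter sets reproduce a
quoted number instead of silently tuning.

Key-residue checks map 1-based reference positions through the alignment
to the target symbol (`-` for a deletion) and compare against expected
residues (defaulting to the reference's own).

## Back-translation and gene design

Two transparent codon-choice modes: `max-frequency` (deterministic;
always the host's most used synonymous codon, ties alphabetical) and
`weighted-sampled` (codons drawn per position with the host's synonymous
usage frequencies; reproducible under a seed). Commercial codon
optimizers are proprietary and irreproducible, so correctness here is
defined as translation equivalence plus constraint satisfaction, never
nucleotide identity with any particular synthesized gene.

One stop codon — the host's most frequent — is appended, so a protein of
length `L` yields a CDS of `3(L+1)` nt. Forbidden motifs (default BamHI
`GGATCC` and EcoRI `GAATTC`, because designs are cloned between those
sites) are scanned on both strands; a hit is removed by trying synonymous
substitutions of the codons covering the motif in order of increasing
usage-frequency loss, accepting the first that clears the span without
increasing the total hit count. If no single-codon substitution clears a
hit the design fails loudly (`DesignInfeasibleError` naming the position)
rather than emitting a gene that cannot be cloned.

The bundled codon-usage table is a representative *Pseudomonas putida*
(GC-rich host) table with fractions rounded from genome-wide KT2440-style
codon statistics; it ships as plain TSV (codon, amino acid, fraction
within its synonymous family) and any organism's table can be supplied in
the same format. No result in this package depends on the exact
fractions, only on their ranking and rough magnitudes.

## Pathway arithmetic

Molar masses are fixed at 165.19 (L-Phe), 148.16 (tCA) and 104.15 g/mol
(styrene) — standard values, overridable in the config — with a 1:1:1
molar mapping along the pathway. Conversions are `x · M_to / M_from`,
yields are `mg product / g substrate`, and annualization multiplies a
daily rate by 365 and rounds to 2 significant figures by default.
`conversion_fraction` divides observed product by the stoichiometric
maximum of the consumed substrate; values above 1 (possible only through
measurement noise) are flagged with a warning but never clamped, so noisy
data stay visible.

Initial rates are the OLS slope over all samples with `t ≤ window`
(default 2 h, boundary inclusive — "the first two hours" includes the 2 h
sample). OLS over the window is used rather than a two-point slope
because it uses all early samples and is unbiased under additive noise;
fewer than two in-window samples is an error, not a silent NaN.

## Synthetic data: what it emulates, and what it does not

`simulate_family` evolves `n` members independently from one random
ancestor: per-site substitutions uniform over the 19 alternative residues,
and indels modelled as deletions only, in the ancestor coordinate frame,
with geometric lengths. Deletions-only keeps the family exactly aligned
by construction, so alignment error is excluded from tests by design. A
uniform substitution model (no rate matrix, no site-rate heterogeneity,
no tree structure) is a deliberate simplification: the consensus
procedure consumes only column frequencies, so a richer evolutionary
model would add realism but no additional test power.

`simulate_design_study` assembles a complete stand-in study: a random
503-residue reference carrying the canonical FDC-family key residues
(I189, Q192, I330, F397, I398); a high-identity tier of 8 homologs with
measured identity in (0.65, 0.88) and all key residues conserved, of
which a plurality share one deleted column (so the tier's consensus is
502 residues — one shorter than the reference, by the gap-deletion rule);
and a broader tier of 66 homologs with identity in (0.52, 0.58) carrying
Y397/T398. Because alignment-based identity runs slightly above
`1 − substitution rate` (the aligner can gap out runs of mismatches),
each member's substitution rate is steered by feedback from its measured
identity until it lands in the tier's band; this is deterministic given
the seed. Everything is synthetic — no real enzyme sequence is used or
approximated — so passing tests demonstrate that the machinery
(stratification, rules, mapping, constraints) behaves as specified, not
that any particular natural enzyme family yields a particular design.

`simulate_bioconversion` produces a substrate trace that falls linearly
at `true_rate` until `plateau_time` and then holds, with the product
mirroring consumed substrate under pathway stoichiometry, i.i.d. Gaussian
noise added per sample, and concentrations floored at zero. Defaults
(rate 26 mg/L/h, ~100 mg/L initial substrate, sampling dense in the first
two hours) mirror a resting-cell decarboxylase assay; 26 mg/L/h is a
representative value for such assays near their pH/temperature optimum.
The floor at zero introduces a small bias only when noise is large
relative to concentration, which the default settings avoid.

## Problem sizes and numerical choices

The test suite and acceptance script run at the scale of the design
workflow itself: families of 8–74 members × ~500 columns, 10,000
randomized small families for the brute-force consensus cross-check,
1,000 random proteins (≤ 600 aa) for back-translation round-trips, and
200 seeded kinetics simulations for rate-recovery statistics; the whole
suite completes in well under a minute on one core. Floating-point
comparisons in pathway arithmetic use exact formulas (no iterative
fitting); codon-frequency validation tolerates 1e-6 per synonymous
family to absorb rounding in supplied tables.

## Known limitations

* No MSA construction: alignments are inputs (by design — computing them
  is an external, well-served step), and insertions relative to the query
  frame are not simulated.
* The difference metric and identity depend on alignment parameters for
  diverged pairs; the penalty-grid report documents, but cannot remove,
  that sensitivity.
* Back-translation does not attempt mRNA-structure or GC-window shaping,
  and motif removal considers single-codon substitutions only (sufficient
  for 6-mer restriction sites, not guaranteed for heavily overlapping
  motif sets).
* The kinetics model is piecewise linear; enzymatic saturation curves,
  lag phases, and product degradation are out of scope.
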
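# Relative synonymous codon usage for Pseudomonas putida (GC-rich host).
# Fractions are within each amino-acid family and sum to 1.0 per amino acid.
# Values are rounded genome-wide KT2440-style fractions; see docs/methods.md.
# codon	amino_acid	fraction
GCC	A	0.47
GCG	A	0.28
GCA	A	0.14
GCT	A	0.11
CGC	R	0.44
CGG	R	0.21
CGT	R	0.17
CGA	R	0.09
AGG	R	0.05
AGA	R	0.04
AAC	N	0.73
AAT	N	0.27
GAC	D	0.62
GAT	D	0.38
TGC	C	0.69
TGT	C	0.31
CAG	Q	0.73
CAA	Q	0.27
GAA	E	0.52
GAG	E	0.48
GGC	G	0.52
GGT	G	0.20
GGG	G	0.15
GGA	G	0.13
CAC	H	0.62
CAT	H	0.38
ATC	I	0.61
ATT	I	0.31
ATA	I	0.08
CTG	L	0.54
CTC	L	0.16
TTG	L	0.10
CTT	L	0.08
CTA	L	0.08
TTA	L	0.04
AAG	K	0.62
AAA	K	0.38
ATG	M	1.00
TTC	F	0.65
TTT	F	0.35
CCG	P	0.42
CCC	P	0.25
CCT	P	0.18
CCA	P	0.15
AGC	S	0.29
TCC	S	0.22
TCG	S	0.19
AGT	S	0.12
TCT	S	0.10
TCA	S	0.08
ACC	T	0.48
ACG	T	0.23
ACT	T	0.16
ACA	T	0.13
TGG	W	1.00
TAC	Y	0.60
TAT	Y	0.40
GTG	V	0.42
GTC	V	0.28
GTT	V	0.18
GTA	V	0.12
TGA	*	0.51
TAA	*	0.29
TAG	*	0.20
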
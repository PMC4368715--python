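# Total codon usage across the 13 protein-coding genes of the Strigamia
# maritima mitochondrial genome (invertebrate mitochondrial code, table 5).
# Counts include initiation and termination codons.
codon	aa	frequency
TTT	F	226
TTC	F	61
TTA	L	184
TTG	L	82
CTT	L	81
CTC	L	23
CTA	L	136
CTG	L	19
ATT	I	195
ATC	I	91
ATA	M	169
ATG	M	57
GTT	V	117
GTC	V	16
GTA	V	79
GTG	V	53
TCT	S	96
TCC	S	31
TCA	S	71
TCG	S	10
CCT	P	44
CCC	P	54
CCA	P	59
CCG	P	6
ACT	T	41
ACC	T	55
ACA	T	129
ACG	T	8
GCT	A	62
GCC	A	57
GCA	A	83
GCG	A	14
TAT	Y	82
TAC	Y	53
TAA	*	8
TAG	*	5
CAT	H	39
CAC	H	43
CAA	Q	61
CAG	Q	15
AAT	N	47
AAC	N	56
AAA	K	65
AAG	K	17
GAT	D	32
GAC	D	35
GAA	E	48
GAG	E	37
TGT	C	25
TGC	C	16
TGA	W	71
TGG	W	35
CGT	R	12
CGC	R	5
CGA	R	35
CGG	R	10
AGT	S	25
AGC	S	15
AGA	S	60
AGG	S	15
GGT	G	59
GGC	G	47
GGA	G	67
GGG	G	122
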
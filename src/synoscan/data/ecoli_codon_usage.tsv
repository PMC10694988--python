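codon	amino_acid	usage_per_1000
AAA	K	33.6
AAC	N	21.7
AAG	K	10.3
AAT	N	17.7
ACA	T	7.1
ACC	T	23.4
ACG	T	14.4
ACT	T	9.0
AGA	R	2.1
AGC	S	16.1
AGG	R	1.2
AGT	S	8.8
ATA	I	4.2
ATC	I	25.1
ATG	M	27.9
ATT	I	30.3
CAA	Q	15.3
CAC	H	9.7
CAG	Q	28.8
CAT	H	12.9
CCA	P	8.4
CCC	P	5.5
CCG	P	23.2
CCT	P	7.0
CGA	R	3.6
CGC	R	22.0
CGG	R	5.4
CGT	R	20.9
CTA	L	3.9
CTC	L	11.0
CTG	L	52.6
CTT	L	11.0
GAA	E	39.4
GAC	D	19.1
GAG	E	17.8
GAT	D	32.1
GCA	A	20.1
GCC	A	25.5
GCG	A	33.6
GCT	A	15.3
GGA	G	8.0
GGC	G	29.6
GGG	G	11.1
GGT	G	24.7
GTA	V	10.8
GTC	V	15.3
GTG	V	26.4
GTT	V	18.3
TAA	*	2.0
TAC	Y	12.2
TAG	*	0.2
TAT	Y	16.2
TCA	S	7.2
TCC	S	8.6
TCG	S	8.9
TCT	S	8.5
TGA	*	1.0
TGC	C	6.4
TGG	W	15.2
TGT	C	5.2
TTA	L	13.9
TTC	F	16.6
TTG	L	13.7
TTT	F	22.2
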
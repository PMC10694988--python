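anticodon	amino_acid	gene_copy_number	decodes_override
AGC	A	0	
GGC	A	2	
TGC	A	3	
CGC	A	0	
ACG	R	4	
GCG	R	0	
TCG	R	0	
CCG	R	1	
TCT	R	1	
CCT	R	1	
ATT	N	0	
GTT	N	4	
ATC	D	0	
GTC	D	3	
ACA	C	0	
GCA	C	1	
TTG	Q	2	
CTG	Q	2	
TTC	E	4	
CTC	E	0	
ACC	G	0	
GCC	G	4	
TCC	G	1	
CCC	G	1	
ATG	H	0	
GTG	H	1	
AAT	I	0	
GAT	I	3	
AAA	F	0	
GAA	F	2	
AAG	L	0	
GAG	L	1	
TAG	L	1	
CAG	L	4	
TAA	L	1	
CAA	L	1	
TTT	K	6	
CTT	K	0	
CAT	M	8	
AGG	P	0	
GGG	P	1	
TGG	P	1	
CGG	P	1	
AGA	S	0	
GGA	S	2	
TGA	S	1	
CGA	S	1	
ACT	S	0	
GCT	S	1	
AGT	T	0	
GGT	T	2	
TGT	T	1	
CGT	T	1	
CCA	W	1	
ATA	Y	0	
GTA	Y	3	
AAC	V	0	
GAC	V	2	
TAC	V	5	
CAC	V	0	
CAT_ile2	I	1	ATA
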
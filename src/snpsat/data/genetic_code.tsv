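codon	symbol	name	group
AAA	K	Lys	POSITIVE
AAC	N	Asn	POLAR
AAG	K	Lys	POSITIVE
AAT	N	Asn	POLAR
ACA	T	Thr	POLAR
ACC	T	Thr	POLAR
ACG	T	Thr	POLAR
ACT	T	Thr	POLAR
AGA	R	Arg	POSITIVE
AGC	S	Ser	POLAR
AGG	R	Arg	POSITIVE
AGT	S	Ser	POLAR
ATA	I	Ile	HYDROPHOBIC
ATC	I	Ile	HYDROPHOBIC
ATG	M	Met	HYDROPHOBIC
ATT	I	Ile	HYDROPHOBIC
CAA	Q	Gln	POLAR
CAC	H	His	POSITIVE
CAG	Q	Gln	POLAR
CAT	H	His	POSITIVE
CCA	P	Pro	SPECIAL
CCC	P	Pro	SPECIAL
CCG	P	Pro	SPECIAL
CCT	P	Pro	SPECIAL
CGA	R	Arg	POSITIVE
CGC	R	Arg	POSITIVE
CGG	R	Arg	POSITIVE
CGT	R	Arg	POSITIVE
CTA	L	Leu	HYDROPHOBIC
CTC	L	Leu	HYDROPHOBIC
CTG	L	Leu	HYDROPHOBIC
CTT	L	Leu	HYDROPHOBIC
GAA	E	Glu	NEGATIVE
GAC	D	Asp	NEGATIVE
GAG	E	Glu	NEGATIVE
GAT	D	Asp	NEGATIVE
GCA	A	Ala	HYDROPHOBIC
GCC	A	Ala	HYDROPHOBIC
GCG	A	Ala	HYDROPHOBIC
GCT	A	Ala	HYDROPHOBIC
GGA	G	Gly	SPECIAL
GGC	G	Gly	SPECIAL
GGG	G	Gly	SPECIAL
GGT	G	Gly	SPECIAL
GTA	V	Val	HYDROPHOBIC
GTC	V	Val	HYDROPHOBIC
GTG	V	Val	HYDROPHOBIC
GTT	V	Val	HYDROPHOBIC
TAA	*	Stp	STOP
TAC	Y	Tyr	HYDROPHOBIC
TAG	*	Stp	STOP
TAT	Y	Tyr	HYDROPHOBIC
TCA	S	Ser	POLAR
TCC	S	Ser	POLAR
TCG	S	Ser	POLAR
TCT	S	Ser	POLAR
TGA	*	Stp	STOP
TGC	C	Cys	SPECIAL
TGG	W	Trp	HYDROPHOBIC
TGT	C	Cys	SPECIAL
TTA	L	Leu	HYDROPHOBIC
TTC	F	Phe	HYDROPHOBIC
TTG	L	Leu	HYDROPHOBIC
TTT	F	Phe	HYDROPHOBIC
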
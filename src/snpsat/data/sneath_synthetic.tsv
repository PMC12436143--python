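	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
A	0	34	22	25	14	25	27	18	27	22	22	32	21	27	16	14	16	36	29	17
R	34	0	22	31	33	19	28	36	13	34	32	5	28	31	43	29	25	25	22	34
N	22	22	0	14	24	10	18	22	18	32	30	21	26	31	18	13	12	32	25	29
D	25	31	14	0	27	19	9	25	25	34	32	30	28	33	22	20	19	34	28	31
C	14	33	24	27	0	26	28	20	27	21	20	31	18	25	21	18	17	34	29	17
Q	25	19	10	19	26	0	17	27	15	30	28	18	23	27	19	18	14	26	20	28
E	27	28	18	9	28	17	0	29	23	32	30	28	26	30	43	23	20	29	24	31
G	18	36	22	25	20	27	29	0	30	34	33	34	31	37	21	16	20	43	36	29
H	27	13	18	25	27	15	23	30	0	30	28	12	24	26	22	23	19	24	18	29
I	22	34	32	34	21	30	32	34	30	0	5	33	13	13	29	28	24	26	23	9
L	22	32	30	32	20	28	30	33	28	5	0	31	12	12	28	27	23	24	21	9
K	32	5	21	30	31	18	28	34	12	33	31	0	27	29	26	28	24	25	21	32
M	21	28	26	28	18	23	26	31	24	13	12	27	0	14	25	24	20	22	18	14
F	27	31	31	33	25	27	30	37	26	13	12	29	14	0	30	30	25	17	16	17
P	16	43	18	22	21	19	43	21	22	29	28	26	25	30	0	18	17	33	27	26
S	14	29	13	20	18	18	23	16	23	28	27	28	24	30	18	0	9	36	29	24
T	16	25	12	19	17	14	20	20	19	24	23	24	20	25	17	9	0	30	23	21
W	36	25	32	34	34	26	29	43	24	26	24	25	22	17	33	36	30	0	11	29
Y	29	22	25	28	29	20	24	36	18	23	21	21	18	16	27	29	23	11	0	25
V	17	34	29	31	17	28	31	29	29	9	9	32	14	17	26	24	21	29	25	0
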
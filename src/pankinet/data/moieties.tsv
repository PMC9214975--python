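id	name	smarts
1	nitrile (triple-bonded nitrogen)	C#N
2	primary amine	[NX3;H2;!$(NC=O)]
3	secondary amine	[NX3;H1;!$(NC=O)]
4	tertiary amine	[NX3;H0;!$(NC=O);!$(N=*);!n]
5	aromatic amine	[NX3;$(N-c)]
6	amide	C(=O)N
7	carboxylic acid	C(=O)[OX2H1]
8	ester	C(=O)O[#6]
9	ketone	[#6]C(=O)[#6]
10	aldehyde	[CX3H1]=O
11	aliphatic alcohol	[OX2H][CX4]
12	phenol	[OX2H]c
13	ether	[OD2]([#6])[#6]
14	thioether	[SD2]([#6])[#6]
15	sulfonamide	S(=O)(=O)N
16	sulfonyl	S(=O)(=O)
17	nitro	[N+](=O)[O-]
18	fluorine	F
19	chlorine	Cl
20	bromine	Br
21	iodine	I
22	trifluoromethyl	C(F)(F)F
23	urea	NC(=O)N
24	guanidine	NC(=N)N
25	aromatic ring nitrogen	n
26	aromatic ring oxygen	o
27	aromatic ring sulfur	s
28	halogen on aromatic ring	c[F,Cl,Br,I]
29	any aromatic atom	[a]
30	heteroatom in ring	[!#6;R]
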
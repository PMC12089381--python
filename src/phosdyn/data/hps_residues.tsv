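code	name	mass	sigma	lambda	charge	source
A	ALA	71.08	0.504	0.73	0	hps
R	ARG	156.2	0.656	0.0	1	hps
N	ASN	114.1	0.568	0.432	0	hps
D	ASP	115.1	0.558	0.378	-1	hps
C	CYS	103.1	0.548	0.595	0	hps
Q	GLN	128.1	0.602	0.514	0	hps
E	GLU	129.1	0.592	0.459	-1	hps
G	GLY	57.05	0.45	0.649	0	hps
H	HIS	137.1	0.608	0.514	0	hps
I	ILE	113.2	0.618	0.973	0	hps
L	LEU	113.2	0.618	0.973	0	hps
K	LYS	128.2	0.636	0.514	1	hps
M	MET	131.2	0.618	0.838	0	hps
F	PHE	147.2	0.636	1.0	0	hps
P	PRO	97.12	0.556	1.0	0	hps
S	SER	87.08	0.518	0.595	0	hps
T	THR	101.1	0.562	0.676	0	hps
W	TRP	186.2	0.678	0.946	0	hps
Y	TYR	163.2	0.646	0.865	0	hps
V	VAL	99.07	0.586	0.892	0	hps
p	SEP	167.05	0.56	0.45	-2	package_default
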
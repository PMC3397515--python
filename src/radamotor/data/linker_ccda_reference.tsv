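residue_id	residue_name	ccda_phi	ccda_psi
71	ILE	0	0
72	ARG	0	360
73	PHE	360	0
74	LYS	0	0
75	THR	360	360
76	ALA	0	360
77	LEU	0	360
78	GLU	0	360
79	VAL	0	360
80	LYS	360	0
81	LYS	360	360
82	GLU	0	0
83	ARG	0	0
84	MET	360	0
85	ASN	0	360
86	VAL	360	360
87	LYS	0	720
88	LYS	0	0
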
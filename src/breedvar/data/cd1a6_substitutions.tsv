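# Published amino-acid substitutions in the eqCD1a6 coding sequence
# (in-group consensus vs reference), one row per changed codon:
# 1-based residue position, reference and substituted residues, exon.
aa_pos	ref_aa	alt_aa	exon
6	F	L	Exon 1
33	S	I	Exon 2
39	P	R	Exon 2
41	R	W	Exon 2
60	N	S	Exon 2
64	S	T	Exon 2
65	F	L	Exon 2
67	F	Y	Exon 2
78	S	N	Exon 2
79	E	K	Exon 2
81	L	M	Exon 2
84	I	M	Exon 2
88	F	S	Exon 2
98	I	V	Exon 2
109	A	E	Exon 2
113	Q	H	Exon 3
116	L	V	Exon 3
117	A	T	Exon 3
118	M	K	Exon 3
132	A	M	Exon 3
139	S	L	Exon 3
142	I	A	Exon 3
144	I	F	Exon 3
157	S	R	Exon 3
164	G	R	Exon 3
165	R	L	Exon 3
171	V	I	Exon 3
172	F	I	Exon 3
174	E	G	Exon 3
175	T	I	Exon 3
176	W	T	Exon 3
219	H	R	Exon 4
225	H	Q	Exon 4
228	S	G	Exon 4
242	K	E	Exon 4
243	K	Q	Exon 4
301	T	M	Exon 5
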
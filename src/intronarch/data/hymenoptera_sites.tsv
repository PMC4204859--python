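species	family	i1h	i2h	i3h	i4h	total_is	n_introns	discrepant_total
A_mellifera	Apidae	2/49	2/85		0/109	243	3	0
B_impatiens	Apidae	2/101	2/84		0/84	269	3	0
M_rotundata	Megachilidae	2/101	2/75		0/65	241	3	0
A_cephalotes	Formicidae	0/92	2/80	2/96	0/84	352	4	0
S_invicta	Formicidae	2/725	2/84	2/130	0/71	1010	4	0
C_floridanus	Formicidae	2/116	2/77	2/137	0/75	405	4	0
H_saltator	Formicidae	2/145	2/89	2/97	0/271	457	4	1
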
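species	group	i1l	i2l	i3l	i4l	i5l	i6l	i7l	i8l	i9l	i10l	i11l	total_is	n_introns	truncated	open_ended
S_frugiperda	Lepidoptera	2/3459	2/344	2/1645	0/8467	1/3290	2/733	2/1097	0/989	0/494	0/601	0/952	22071	11	0	0
B_mori	Lepidoptera	2/3280	2/2841	2/5599	0/1203	1/1197	2/355	2/483	0/1167	0/1971	0/1188	0/795	20079	11	0	0
D_plexippus	Lepidoptera	2/4756	2/312	2/1263	0/2173	1/512	2/299	2/1177	0/1393	0/468	0/590	0/71	13014	11	0	0
H_melpomene	Lepidoptera	2/1633	2/712	2/1821	0/7380	1/1111	2/204	2/146	0/795		0/129	0/248	14179	10	0	0
T_castaneum	Coleoptera				0/9139	1/52		2/1524		0/8806			21186	5	0	0
A_pisum	Hemiptera				0/67	1/91		2/118		0/62			752	7	0	0
P_humanus	Phtiraptera			2/342	0/82	1/215		2/295					3507	9	0	0
D_melanogaster	Diptera				0/109			2/65					582	3	0	0
C_pipiens	Diptera							2/62	0/98				160	2	0	0
L_longipalpis	Diptera							2/94	0/438				3290	3	1	1
M_occidentallis	Mesostigmata									0/210			1581	8	0	0
T_urticae	Trombidiformes												1173	6	0	0
D_pulex	Cladocera			2/65	0/60	1/61		2/55					320	5	0	0
L_salmonis	Siphonostomatoida												0	0	0	0
S_maritima	Geophilomorpha							2/292		0/56			2591	6	0	0
C_intestinalis_A	Enterogona			2/836		1/906		2/820		0/447	0/5797		10989	10	0	0
H_sapiens	Primate			2/13118		1/52295		2/2125		0/8711			130359	8	0	0
R_norvegicus	Rodentia			2/19848		1/36598		2/1403		0/11243			131971	8	0	0
B_taurus	Artiodactyla			2/14139		1/40145		2/4795		0/11832			173134	8	0	0
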
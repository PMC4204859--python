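species	phylum	i1l	i2l	i3l	i4l	i4c	i5l	i6l	i7l	i8l	i7c	i9l	i10l	i11l	total_is	n_introns	truncated	open_ended
H_sapiens	Chordata			X		+	X		X		+	X			130359	8	0	0
G_gallus	Chordata			X		+	X		X		+	X			36774	8	0	0
M_gallopavo	Chordata			X		+	X		X		+	X			37003	8	0	0
T_guttata	Chordata			X		+	X		X		+	X			43603	8	0	0
A_carolinensis	Chordata			X		+	X		X		+	X			67279	8	0	0
X_tropicalis	Chordata			X		+	X		X		+	X			72102	8	0	0
D_rerio_B	Chordata			X		+	X		X		+	X			88524	8	0	0
T_rubipres	Chordata			X		+	X		X		+	X			23935	8	0	0
O_latipes	Chordata			X		+	X		X		+	X			44674	8	0	0
O_niloticus	Chordata			X		+	X		X		+	X			45900	8	0	0
S_purpuratus	Echinodermata			X		+	X		X		+	X			58902	8	0	0
S_kowalevskii_A	Hemichordata			X		+	X		X		+	X			21376	8	0	0
T_spiralis	Nematoda							X	X			X			1122	7	0	0
C_brenneri	Nematoda										+	X			652	9	0	0
L_loa	Nematoda										+				3347	9	0	0
B_malayi	Nematoda										+				2417	9	0	0
W_bancrofti	Nematoda										+				2954	10	0	0
A_suum	Nematoda										+				13589	10	0	0
C_teleta	Annelida			X		+			X		+	X			1183	7	0	0
T_adhaerens	Placozoa								X		+	X			682	3	1	1
H_magnipapillata	Cnidaria								X		+	X			13440	4	0	0
N_vectensis	Cnidaria								X		+	X			2492	4	0	0
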
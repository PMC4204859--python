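node	age_mya
R0	855
N1	783
N2	600
N3	372
N3x	300
N3y	265
Nematoda	0
Cnidaria	0
Chordata	0
Chilopoda	0
Lepidoptera	0
Diptera	0
Hymenoptera	0
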
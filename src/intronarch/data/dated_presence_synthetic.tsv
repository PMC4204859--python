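site	Nematoda	Cnidaria	Chordata	Chilopoda	Lepidoptera	Diptera	Hymenoptera
i7c	1	1	1	1	0	0	0
i9l	1	1	1	1	1	0	0
i7l	0	1	1	1	1	1	0
i3l	0	0	1	0	1	0	0
i5l	0	0	1	0	1	0	0
i4c	0	0	1	1	0	0	0
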
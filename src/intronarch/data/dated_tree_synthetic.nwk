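[&R] (Nematoda:855,(Cnidaria:783,(Chordata:600,(Lepidoptera:372,(Chilopoda:300,(Diptera:265,Hymenoptera:265)N3y:35)N3x:72)N3:228)N2:183)N1:72)R0;
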
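candidate	context
ATG1	CGCCGCGACA
ATG2	UGACUACUUU
ATG3	CUACUUUAUG
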
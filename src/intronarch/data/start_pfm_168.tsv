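position	A	U	G	C
-10	43	26	14	17
-9	36	34	17	13
-8	27	29	14	30
-7	35	27	7	31
-6	27	31	28	14
-5	22	41	12	25
-4	39	11	7	43
-3	88	0	10	2
-2	64	13	3	20
-1	57	6	11	26
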
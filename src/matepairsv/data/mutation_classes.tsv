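effect_class	patient1	patient2	patient3	patient4	patient5	patient6
nonsynonymous coding	20	30	31	44	101	34
synonymous coding	13	12	0	0	0	0
insertion/deletion	1	4	0	6	0	2
stop gained	0	3	3	2	6	2
start gained	0	1	0	0	0	0
codon insertion	0	1	0	0	0	1
codon deletion	0	0	0	0	0	1
splice site donor	0	0	1	0	1	2
splice site acceptor	0	0	0	0	4	0
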
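patient	gene	effect_class
patient2	CSPG4	nonsynonymous coding
patient5	CSPG4	nonsynonymous coding
patient1	GRIN3A	nonsynonymous coding
patient4	GRIN3A	nonsynonymous coding
patient4	PLXNB3	nonsynonymous coding
patient5	PLXNB3	nonsynonymous coding
patient1	BAP1	nonsynonymous coding
patient3	ERRFI1	stop gained
patient6	IDH2	nonsynonymous coding
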
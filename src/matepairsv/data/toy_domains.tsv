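gene	domain	start	end
FGFR2	protein tyrosine kinase	41551	44400
TACC3	coiled-coil	8001	9900
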
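allele_a	allele_b
Ss9	Sp1
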
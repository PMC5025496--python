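female	male	allele_a	allele_b	count
OKA1	OKA5	So1	So5	13
OKA1	OKA5	So2	So5	17
OKA1	OKA9	So1	So4	18
OKA1	OKA9	So2	So4	11
OKA3	OKA5	So1	So5	16
OKA3	OKA5	So2	So5	13
OKA3	OKA9	So1	So4	14
OKA3	OKA9	So2	So4	14
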
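species	accession	allele	clones
S. okadae	OKA1	So1	3
S. okadae	OKA1	So2	4
S. okadae	OKA3	So1	2
S. okadae	OKA3	So2	3
S. okadae	OKA5	So1	13
S. okadae	OKA5	So5	2
S. okadae	OKA7	So3	10
S. okadae	OKA9	So1	7
S. okadae	OKA9	So4	2
S. stenotomum	STN4679	Ss1	3
S. stenotomum	STN4679	Ss9	2
S. stenotomum	STN4679-72	Ss5	4
S. stenotomum	STN4711-61	Ss2	3
S. stenotomum	STN4711-61	Ss3	2
S. stenotomum	STN4741	Ss4	8
S. stenotomum	STN4741	Ss10	1
S. stenotomum	STN4741-135	Ss8	4
S. stenotomum	STN4786-80	Ss6	3
S. stenotomum	STN4786-80	Ss7	4
S. phureja	DB226	Sp1	4
S. phureja	DB337	Sp2	4
S. phureja	DB536	Sp2	4
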
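female	male	berry_set	seeds_per_berry
OKA1	OKA1	0	
OKA1	OKA3	0	
OKA1	OKA5	1	106
OKA1	OKA7	1	125
OKA1	OKA9	1	125
OKA3	OKA1	0	
OKA3	OKA3	0	
OKA3	OKA5	1	50
OKA3	OKA7	1	71
OKA3	OKA9	1	82
OKA5	OKA1	1	19
OKA5	OKA3	1	60
OKA5	OKA5	0	
OKA5	OKA7	1	37
OKA5	OKA9	1	87
OKA7	OKA1	1	52
OKA7	OKA3	1	50
OKA7	OKA5	1	106
OKA7	OKA7	0	
OKA7	OKA9	1	90
OKA9	OKA1	1	113
OKA9	OKA3	1	115
OKA9	OKA5	1	100
OKA9	OKA7	1	79
OKA9	OKA9	0	
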
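	So1	So2	So3	So4	So5	Ss1	Ss2	Ss3	Ss4	Ss5	Ss6	Ss7	Ss8	Ss9p1	Ss10	Sp2
So1		32.9	42.2	52.3	73.9	43.7	33.5	50.6	41.9	72.0	38.3	41.1	75.8	76.4	51.3	39.6
So2			47.5	38.0	34.8	44.6	48.4	34.4	45.3	37.4	44.1	42.0	35.5	35.5	34.4	45.3
So3				42.3	44.8	44.2	37.7	39.2	43.8	44.8	42.1	43.6	44.2	44.2	39.9	44.7
So4					53.5	40.3	38.0	70.8	40.5	54.8	44.6	38.3	56.8	56.1	72.7	44.6
So5						39.7	33.5	50.6	39.4	84.7	43.5	40.4	86.0	86.6	50.0	44.2
Ss1							42.9	35.9	39.5	39.1	37.2	74.5	39.7	38.4	36.5	37.2
Ss2								33.1	43.5	34.8	36.2	45.5	33.5	33.5	35.0	38.8
Ss3									40.6	53.8	38.4	34.0	53.2	52.6	94.5	40.9
Ss4										40.6	43.8	40.1	41.9	41.3	42.5	48.8
Ss5											43.5	37.7	82.8	84.1	53.2	42.9
Ss6												37.8	41.6	42.2	40.3	80.4
Ss7													39.7	38.4	36.5	39.1
Ss8														87.9	53.8	42.9
Ss9p1															53.8	44.2
Ss10																42.1
Sp2																
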
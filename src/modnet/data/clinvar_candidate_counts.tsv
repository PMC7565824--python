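gene	all	b_lb	p_lp	ci	vus
AKT1	182	94	8	4	76
BRAF	334	125	80	12	117
EGFR	199	54	4	7	134
LIMK1	36	36	0	0	0
PAK1	6	2	3	-	1
PTEN	1567	367	510	22	668
RAF1	412	155	43	17	197
SDC2	-	-	-	-	-
SMARCA4	2310	980	95	81	1154
VCP	170	64	18	10	78
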
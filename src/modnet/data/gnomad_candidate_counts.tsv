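gene	all	missense	synonymous	splice_site	frameshift	inframe_del_ins	intronic	nonsense	stop_lost	start_lost	utr5	utr3
AKT1	932	166	155	80	3	4	435	1	0	0	36	52
BRAF	1073	230	170	56	1	8	561	2	1	0	13	31
EGFR	2000	682	387	117	15	2	867	16	1	0	9	104
LIMK1	1133	322	214	58	5	1	469	3	1	0	44	16
PAK1	774	128	121	58	4	6	401	5	1	0	8	42
PTEN	456	83	77	17	5	0	223	5	0	0	28	18
RAF1	1005	264	145	65	4	2	490	7	0	2	8	18
SDC2	335	102	52	18	5	3	114	0	0	5	22	14
SMARCA4	2575	473	551	164	4	22	1318	0	1	0	9	33
VCP	928	135	191	72	1	1	488	0	0	0	20	20
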
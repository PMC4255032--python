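insertion_id	species	family	superfamily	length_nt	tsd	tsd_class	copy_number_total	copy_number_high	transcriptome_hits	position_class	distance_kb
1	L_chalumnae	CR1	CR1	1622	AT	TSD	5	2	17	IGR	5.9
2	L_chalumnae	CR1	CR1	1060		AT_rich_region	1	1	0	intron	0.7
3	L_chalumnae	CR1	CR1	1097	GAGTCTTGTT	TSD	1	1	4	IGR	4.0
4	L_chalumnae	CR1	CR1	227	CTA	TSD	49	5	1	IGR	9.7
5	L_chalumnae	CR1	CR1	320	TTTAG	TSD	37	5	0	IGR	9.4
6	L_chalumnae	CR1	CR1	303	TATTAGG	TSD	1	1	0	IGR	>70.9
7	L_menadoensis	CR1	CR1	2845	ACTCA	TSD	23	4	24	IGR	>9.0
8	L_menadoensis	CR1	CR1	2821	AAT	TSD	24	24	31	IGR	3.2
9	L_menadoensis	CR1	CR1	1174	AAGTA	TSD	4	4	8	IGR	3.6
10	L_menadoensis	CR1	CR1	1038	CCAT	TSD	74	18	10	IGR	18.3
11	L_menadoensis	CR1	CR1	862	GATTAA	TSD	86	19	6	intron	0.2
12	L_menadoensis	CR1	CR1	1398	TCTA	TSD	57	15	13	IGR	37.5
13	L_menadoensis	CR1	CR1	1019		polyA_region	1	1	0	intron	1.3
14	L_menadoensis	CR1	CR1	385		not_detected	110	14	0	intron	0.4
15	L_menadoensis	CR1	CR1	387	CTATTCC	TSD	109	12	3	intron	6.2
16	L_menadoensis	L1	L1	2168	ACTAATCTTATTTTAA	TSD	2	2	20	IGR	41.6
17	L_menadoensis	L1	L1	1999		not_detected	4	4	19	IGR	0.8
18	L_chalumnae	L2	L2	2219	G	TSD	2	2	0	IGR	3.4
19	L_chalumnae	CoeG-SINE	SINE	1362		not_detected	1	1	16	intron	0.6
20	L_menadoensis	CoeG-SINE	SINE	1018	ATTTT	TSD	1	1	0	IGR	18.0
21	L_chalumnae	LF-SINE	SINE	391	TG	TSD	48	48	0	IGR	33.1
22	L_chalumnae	Gypsy	Gypsy	896	CCCGCAGCGCCCCCCCCAGAGAAT	TSD	1	1	1	IGR	33.1
23	L_menadoensis	ERV	ERV	5091	AGAT	TSD	1	1	41	IGR	10.6
24	L_chalumnae	MITE-like	MITE	225	CCT	TSD	2	2	0	IGR	6.4
25	L_chalumnae	MITE-like	MITE	1311	ATTTCAAG	TSD	1	1	5	IGR	2.8
26	L_chalumnae	Composite	Composite	2303	T	TSD	1	1	5	IGR	90.7
27	L_menadoensis	Composite	Composite	1249		not_detected	1	1	0	IGR	>12.8
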
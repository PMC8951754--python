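rsid	label	annotation	kind	ref	alt	balkan_hom_ref	balkan_het	balkan_hom_alt	medjimurje_hom_ref	medjimurje_het	medjimurje_hom_alt	baranja_hom_ref	baranja_het	baranja_hom_alt	hwe_balkan	hwe_medjimurje	hwe_baranja	hwe_combined
rs1135840	9200 G > C	missense variant	snv	G	C	8	39	51	20	43	44	14	56	46	0.8873	0.1119	0.6276	0.3772
rs28371732	8848 G > A	synonymous variant	snv	G	A	96	0	0	102	1	0	92	0	0	.	0.9605	.	0.9766
rs4987144	8810 C > T	intron variant	snv	C	T	44	44	10	59	36	13	59	42	16	0.8366	0.0538	0.066	0.0363
rs28371730	8604 G > A	intron variant	snv	G	A	40	44	14	45	50	13	50	48	19	0.7361	0.8758	0.2036	0.3834
rs2004511	8602 A > G	intron variant	snv	A	G	37	50	11	30	69	9	45	65	7	0.3336	0.0007	0.0088	0.0001
rs1269631565	8565 dup	intron variant	indel	T	TT	94	4	0	86	22	0	106	11	0	0.8366	0.2386	0.5936	0.2749
rs867985262	8504 G > A	intron variant	snv	G	A	98	0	0	107	1	0	117	0	0	.	0.9614	.	0.9778
rs79596243	8498 A > G	intron variant	snv	A	G	98	0	0	107	1	0	117	0	0	.	0.9614	.	0.9778
rs28371729	8455 C > A	intron variant	snv	C	A	96	2	0	107	1	0	116	1	0	0.9187	0.9614	0.9630	0.9108
rs28578778	8413 T > C	intron variant	snv	T	C	98	0	0	108	0	0	116	1	0	.	.	0.9630	0.9778
rs1985842	8404 A > C	intron variant	snv	A	C	8	40	50	19	45	44	13	58	46	1.000	0.2143	0.4040	0.7101
rs200335621	8199 C > T	synonymous variant	snv	C	T	96	2	0	106	2	0	107	10	0	0.9187	0.9226	0.6292	0.6905
rs141009491	8180 G > C	missense variant	snv	G	C	98	0	0	108	0	0	116	1	0	.	.	0.9630	0.9778
rs28371725	8008 G > A	intron variant	snv	G	A	66	20	5	88	15	0	75	34	4	0.0543	0.4254	0.9517	0.1832
rs16947	7870 C > T	missense variant	snv	C	T	34	35	21	46	47	10	48	42	21	0.0511	0.6876	0.0393	0.0236
rs762158210	7632_7634 del	inframe deletion	indel	GAGAA	GA	67	2	0	37	0	0	23	0	0	0.9028	.	.	0.9293
rs35742686	7569 del	frameshift variant	indel	CAG	CG	92	1	0	97	0	0	95	0	0	0.9584	.	.	0.9763
rs28371717	7503 G > T	missense variant	snv	G	T	98	0	0	108	0	0	116	1	0	.	.	0.9630	0.9778
rs17002852	7490 T > C	synonymous variant	snv	T	C	91	7	0	108	0	0	104	12	1	0.7139	.	0.3395	0.2439
rs2267447	7117 A > G	intron variant	snv	A	G	53	36	9	63	41	4	63	49	5	0.4295	0.3927	0.2320	0.4934
rs3892097	6866 G > A	splice acceptor variant	snv	G	A	57	34	7	74	34	0	71	44	2	0.5398	0.0522	0.0974	0.1578
rs1135824	6769 A > G	missense variant	snv	A	G	92	6	0	108	0	0	117	0	0	0.7546	.	.	0.8662
rs1349481801	6684 C > T	synonymous variant	snv	C	T	98	0	0	108	0	0	116	1	0	.	.	0.9630	0.9778
rs1058164	6681 G > C	synonymous variant	snv	G	C	8	40	50	19	46	43	13	58	46	1.000	0.2803	0.4040	0.7749
rs376056664	6460 T > C	intron variant	snv	T	C	96	1	0	105	0	0	115	0	0	0.9593	.	.	0.9776
rs189736703	6313 G > A	intron variant	snv	G	A	98	0	0	108	0	0	114	1	0	.	.	0.9626	0.9777
rs1081004	6188 G > A	intron variant	snv	G	A	94	3	1	103	2	3	110	2	5	0.0001	0.00002	<1e-5	<1e-5
rs368389952	6089 G > A	intron variant	snv	G	A	86	6	6	108	0	0	117	0	0	<1e-5	.	.	<1e-5
rs1081003	6057 C > T	synonymous variant	snv	C	T	94	4	0	96	12	0	114	3	0	0.8366	0.5410	0.8883	0.5860
rs28371705	6015 C > G	synonymous variant	snv	C	G	91	7	0	108	0	0	115	2	0	0.7139	.	0.9257	0.7996
rs28371704	6002 A > G	missense variant	snv	A	G	91	6	0	108	0	0	115	2	0	0.7553	.	0.9257	0.8214
rs28371703	5992 C > A	intron variant	snv	G	A	95	0	0	108	0	0	116	1	0	.	.	0.9630	0.9777
rs29001678	5289 C > T	noncoding transcript exon variant	snv	C	T	80	2	0	96	0	1	97	2	2	0.9110	0.005	0.001	1.8e-5
rs1081000	5264 A > G	noncoding transcript exon variant	snv	A	G	86	11	0	108	0	0	115	2	0	0.5538	.	0.9257	0.7116
rs1065852	5119 C > T	missense variant	snv	C	T	53	35	10	63	40	5	63	47	7	0.2532	0.6703	0.6483	0.8448
rs138100349	5101 C > T	missense variant	snv	C	T	97	1	0	106	2	0	114	3	0	0.9595	0.9226	0.8883	0.8662
rs769258	5050 G > A	missense variant	snv	G	A	95	3	0	108	0	0	115	2	0	0.8777	.	0.9257	0.8885
rs372204775	4818 G > A	intron variant	snv	G	A	95	2	0	99	9	0	111	6	0	0.9183	0.6514	0.7759	0.6266
rs530422334	4666 A > G	intron variant	snv	A	G	98	0	0	101	7	0	113	4	0	.	0.7278	0.8508	0.7556
rs1080992	4655 G > A	intron variant	snv	G	A	98	0	0	106	2	0	117	0	0	.	0.9226	.	0.9555
rs769811346	4623 G > T	intron variant	snv	G	T	98	0	0	108	0	0	116	1	0	.	.	0.9630	0.9778
rs374672076	4622 G > C	intron variant	snv	G	C	81	17	0	98	10	0	100	17	0	0.3471	0.6139	0.3968	0.1890
rs566383351	4589 C > T	intron variant	snv	C	T	67	31	0	85	23	0	85	32	0	0.0629	0.2155	0.0866	0.0058
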
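diplotype	phenotype	balkan	baranja	medjimurje
*1/*1	NM	6	14	17
*1/*2	NM	8	14	21
*1/*4	IM	16	22	9
*1/*10	NM	1	6	4
*1/*22	IM	1	0	1
*1/*34	NM	1	0	1
*1/*39	NM	1	0	2
*1/*41	NM	10	14	6
*2/*2	NM	10	4	8
*2/*4	IM	9	8	11
*2/*10	NM	2	1	6
*2/*34	NM	0	0	1
*2/*35	NM	1	2	0
*2/*41	NM	8	9	3
*4/*4	PM	7	2	0
*4/*10	IM	2	5	9
*4/*34	IM	0	0	1
*4/*35	IM	1	0	0
*4/*39	IM	1	0	1
*4/*41	IM	4	9	3
*10/*10	IM	0	0	1
*10/*41	IM	1	0	0
*22/*41	IM	0	0	1
*34/*39	NM	1	0	0
*34/*41	NM	0	1	0
*39/*41	NM	0	1	0
*41/*41	IM	4	4	0
*65/*41	IM	0	1	0
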
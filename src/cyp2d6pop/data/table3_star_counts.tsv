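star	function	balkan	baranja	medjimurje
*1	normal	50	84	78
*2	normal	49	42	58
*4	no_function	48	48	34
*10	decreased	6	12	21
*22	uncertain	1	0	2
*34	normal	2	1	3
*35	normal	2	2	0
*39	uncertain	3	1	5
*41	decreased	32	43	13
*65	uncertain	0	1	0
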
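star	function	activity	core	exclude
*1	normal	1	.	.
*2	normal	1	rs16947;rs1135840	.
*4	no_function	0	rs3892097;rs1065852	.
*10	decreased	0.25	rs1065852;rs1135840	rs3892097
*22	uncertain	0	rs138100349	.
*34	normal	1	rs16947	rs1135840
*35	normal	1	rs769258;rs16947;rs1135840	.
*39	uncertain	1	rs1135840	rs16947
*41	decreased	0.5	rs28371725;rs16947;rs1135840	.
*65	uncertain	0.25	rs28371704;rs1065852;rs1135840	rs3892097
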
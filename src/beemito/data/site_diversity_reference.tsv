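region	site	N	Na	Np	Ne	uh
Lima	Barranca	42	3	1	1.215	0.181
Lima	Coayllo	38	3	1	1.936	0.496
Lima	Quilmana	36	9	1	4.909	0.819
Lima	Santa Maria	39	5	1	2.164	0.552
Lima	Sayan	35	5	1	3.840	0.761
Piura	Chulucanas 1	38	5	1	2.597	0.632
Piura	Chulucanas 2	31	6	1	3.302	0.720
Piura	La Matanza 1	14	6	1	5.444	0.879
Piura	La Matanza 2	52	6	1	4.777	0.806
Piura	Piura	31	8	1	3.469	0.735
Junin	La Merced	32	8	1	4.414	0.798
Junin	Perene 1	36	7	1	2.374	0.595
Junin	Perene 2	29	6	1	2.572	0.633
Junin	San Ramon	35	7	1	5.258	0.834
Junin	Vitoc	24	4	1	2.909	0.685
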
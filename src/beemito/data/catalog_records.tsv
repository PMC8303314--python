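name	lineage	sublineage	pattern	family	edits	novel	observed
A1	A	AI	P0Q	A1		0	1
A1e	A	AI	P0Q	A1	160:C>T	0	1
A1t	A	AI	P0Q	A1	99:G>A;139:->A;646:C>T	1	1
A1u	A	AI	P0Q	A1	99:G>A;286:T>C	1	1
A1w	A	AI	P0Q	A1	100:->G;646:C>T	1	1
A4	A	AI	P0QQ	A4		0	0
A4p	A	AI	P0QQ	A4	99:A>G;100:->G;646:C>T	1	1
A4q	A	AI	P0QQ	A4	99:A>G;100:->G;298:->A;646:C>T	1	1
A4s	A	AI	P0QQ	A4	337:->A;646:C>T	1	1
A4t	A	AI	P0QQ	A4	252:T>-;337:->A;646:C>T	1	1
A4u	A	AI	P0QQ	A4	252:T>-;646:C>T	1	1
A4v	A	AI	P0QQ	A4	252:T>-;337:->A;646:C>T;739:A>T	1	1
A4w	A	AI	P0QQ	A4	252:T>-;337:->A;646:C>T;795:A>T	1	1
A30	A	AIII	P1QQ	A30		0	1
A30d	A	AIII	P1QQ	A30	336:C>-	1	1
A30e	A	AIII	P1QQ	A30	86:C>A	1	1
A65	A	AI	P0	A65		1	1
C1	C	none	Q	C2	170:G>A;660:A>G	0	1
C2	C	none	Q	C2		0	1
C2c	C	none	Q	C2	170:G>A	0	1
C2j	C	none	Q	C2	180:G>A	0	1
C2l	C	none	Q	C2	170:G>A;670:A>G	0	1
C3	C	none	Q	C2	190:G>A	0	1
M7	M	none	PQQ	M7		0	0
M7b	M	none	PQQ	M7	84:A>G	1	1
M7c	M	none	PQQ	M7	84:A>G;148:T>C	1	1
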
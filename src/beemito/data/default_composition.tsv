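region	site	haplotype	count
Lima	Barranca	C1	38
Lima	Barranca	C2j	3
Lima	Barranca	A30d	1
Lima	Coayllo	C1	24
Lima	Coayllo	C2j	13
Lima	Coayllo	A30e	1
Lima	Quilmana	C1	11
Lima	Quilmana	C2j	8
Lima	Quilmana	C2c	3
Lima	Quilmana	C3	2
Lima	Quilmana	A4p	4
Lima	Quilmana	A4t	4
Lima	Quilmana	A1	1
Lima	Quilmana	A1e	1
Lima	Quilmana	A30	2
Lima	Santa Maria	C1	12
Lima	Santa Maria	C2j	17
Lima	Santa Maria	C2c	3
Lima	Santa Maria	A4p	5
Lima	Santa Maria	A1t	2
Lima	Sayan	C1	9
Lima	Sayan	C2j	14
Lima	Sayan	C2	4
Lima	Sayan	A4t	6
Lima	Sayan	A30	2
Piura	Chulucanas 1	A4p	20
Piura	Chulucanas 1	A4t	10
Piura	Chulucanas 1	A1	4
Piura	Chulucanas 1	C2j	3
Piura	Chulucanas 1	A4u	1
Piura	Chulucanas 2	A4p	14
Piura	Chulucanas 2	A4t	6
Piura	Chulucanas 2	A1e	4
Piura	Chulucanas 2	A30	2
Piura	Chulucanas 2	M7b	4
Piura	Chulucanas 2	C2c	1
Piura	La Matanza 1	A4p	3
Piura	La Matanza 1	A4t	3
Piura	La Matanza 1	A1	3
Piura	La Matanza 1	A30	2
Piura	La Matanza 1	M7c	2
Piura	La Matanza 1	A65	1
Piura	La Matanza 2	A4p	25
Piura	La Matanza 2	A4t	12
Piura	La Matanza 2	A1	6
Piura	La Matanza 2	A1e	5
Piura	La Matanza 2	A4q	2
Piura	La Matanza 2	C2j	2
Piura	Piura	A4p	10
Piura	Piura	A4t	6
Piura	Piura	A1	4
Piura	Piura	A1e	3
Piura	Piura	A30	4
Piura	Piura	A65	1
Piura	Piura	C2l	2
Piura	Piura	C2c	1
Junin	La Merced	A4p	7
Junin	La Merced	A4t	10
Junin	La Merced	A30	7
Junin	La Merced	A1	2
Junin	La Merced	A1e	2
Junin	La Merced	A65	1
Junin	La Merced	A1w	2
Junin	La Merced	C2c	1
Junin	Perene 1	A4p	9
Junin	Perene 1	A4t	13
Junin	Perene 1	A30	7
Junin	Perene 1	A1	2
Junin	Perene 1	A1e	2
Junin	Perene 1	A4s	2
Junin	Perene 1	C2c	1
Junin	Perene 2	A4p	6
Junin	Perene 2	A4t	9
Junin	Perene 2	A30	8
Junin	Perene 2	A1	2
Junin	Perene 2	A1e	2
Junin	Perene 2	A4v	2
Junin	San Ramon	A4p	8
Junin	San Ramon	A4t	8
Junin	San Ramon	A30	10
Junin	San Ramon	A1	1
Junin	San Ramon	A1e	1
Junin	San Ramon	A1u	6
Junin	San Ramon	C2c	1
Junin	Vitoc	A4p	6
Junin	Vitoc	A4t	9
Junin	Vitoc	A30	7
Junin	Vitoc	A4w	2
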
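# id	sry_snp	umn2303_size	srym18_size	tri	str_snp	mono	par	pyr	orn	cat	rupW	rupC	rupE	tat	cap	bal	asi	cau
Y-Rpyr1	A	130	102	2	A	9	17 (3)	9 (4)	0	0	0	0	0	0	0	0	0	0
Y-Rpyr2	A	125	102	2	A	9	1 (1)	7 (3)	0	0	0	0	0	0	0	0	0	0
Y-Rpyr3	A	125	105	2	A	12	0	0	6 (1)	0	0	0	0	0	0	0	0	0
Y-RrupA1	G	125	109	3	T	13	0	0	0	0	1 (1)	6 (1)	1	0	0	1 (1)	0	0
Y-RrupA2	G	125	110	3	T	14	0	0	0	1 (1)	2 (1)	0	2 (1)	5 (4)	6 (4)	3 (2)	0	0
Y-RrupA3	G	125	111	3	T	15	0	0	0	0	5 (1)	4 (1)	0	0	0	0	0	0
Y-RrupA4	G	125	112	3	T	16	0	0	0	4 (1)	1 (1)	0	0	0	0	0	0	0
Y-RrupB1	G	125	111	4	T	12	0	0	0	0	0	0	0	0	0	0	0	3 (3)
Y-RrupB2	G	125	113	4	T	14	0	0	0	0	0	0	0	0	0	0	1 (1)	0
Y-RrupC	G	125	112	5	T	10	0	0	0	0	0	0	0	0	0	0	0	1 (1)
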
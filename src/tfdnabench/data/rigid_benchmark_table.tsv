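block	name	pdb_id	resolution	scop	protein_chains	oligo_state	dna_chains	nrbc	bsa
Easy	ZIF268	1aay	1.60	g.37.1.1	A	monomer	B,C	13	960.81
Easy	Max	1an2	2.90	a.38.1.1	A,C	homodimer	B,D	10	933.75
Easy	Papillomavirus E2	1jj4	2.40	d.58.8.1	A,B	heterodimer	C,D	10	839.96
Easy	QacR	1jt0	2.90	a.4.1.9	B,D	homodimer	E,F	12	1085.51
Easy	Lambda repressor	1lmb	1.80	a.35.1.2	3,4	homodimer	1,2	10	1105.4
Easy	TATA-binding	1qn4	1.86	d.129.1.1	B	monomer	E,F	15	1107.51
Easy	Tet repressor	1qpi	2.50	a.4.1.9	A,C	homodimer	B,M	14	973.49
Easy	MecI	1sax	2.80	a.4.5.39	A,B	homodimer	C,D	12	1130.16
Easy	Trep repressor	1tro	1.90	a.4.12.1	A,C	homodimer	I,J	12	1243.06
Easy	OhrR	1z9c	2.64	a.4.5.28	C,D	homodimer	I,J	12	1669.81
Easy	Phi lambda phage cII	1zs4	1.70	a.39.1.9	A,B,C,D	homotetramer	U,T	14	1043.06
Easy	p53	2ac0	1.80	b.2.5.2	A,B,C,D	homotetramer	E,F,G,H	21	1921.76
Easy	CAP	2cgp	2.20	a.4.5.4	A,F	homodimer	B,C,D,E	10	944.43
Easy	LRP/ASNC family protein	2e1c	2.10	a.4.5.32	A,F	homodimer	B,D	11	803.23
Easy	IdeR	2it0	2.60	a.4.5.24	C,D	homodimer	E,F	11	1123.8
Easy	Phi 434 repressor	2or1	2.50	a.35.1.2	R,L	homodimer	A,B	17	1021.78
Easy	CgmR	2yvh	2.50	NA	C,D	homodimer	E,F,G,H	10	1056.55
Easy	Controller protein	3clc	2.80	a.35.1.3	C,D	homodimer	E,F	14	1002.57
Easy	HipB	3dnv	2.68	NA	B,C	homodimer	E,T	10	990.24
Easy	CprK	3e6c	1.80	a.4.5.4	C,D	homodimer	A,B,E,F	12	1059.42
Easy	NrtR	3gz6	2.90	NA	A,B	homodimer	C,D	15	1845.4
Hard	CopG repressor	1b01	2.56	a.43.1.3	A,B	homodimer	E,F	5	573.31
Hard	RXR-alpha	1by4	2.10	g.39.1.2	A,B	homodimer	E,F	8	1031.94
Hard	Met repressor	1cma	2.80	a.43.1.5	A,B	homodimer	C,D	4	693.13
Hard	PhoB	1gxp	2.50	a.4.6.1	A	monomer	C,D	7	739.09
Hard	Myb	1h8a	2.23	a.4.1.3	C	monomer	D,E	8	738.59
Hard	AML1 Runt domain	1hjc	2.65	b.2.5.6	D	monomer	E,F	6	540.76
Hard	MtaN	1r8d	2.70	a.6.1.3	A,B	homodimer	C,D	8	1338.92
Hard	Sigma subunit domain 4	1rio	2.30	a.4.13.2	H	monomer	U,T	6	423.27
Hard	Prospero	1xpx	2.80	a.4.1.1	A	monomer	C,D	3	325.79
Hard	Put3	1zme	2.50	g.38.1.1	C,D	homodimer	A,B	5	1211.56
Hard	Omega repressor	2bnw	2.45	a.43.1.4	A,B	homodimer	E,F	4	519.26
Hard	ILF	2c6y	2.40	a.4.5.14	A	monomer	C,D	8	814.94
Hard	Phi 29 protein p4	2fio	2.70	NA	A,B	homodimer	C,D	4	903.33
Hard	IRF-2	2irf	2.20	a.4.5.23	L	monomer	C,D	6	668.45
Hard	PutA	2rbf	2.25	NA	A,B	homodimer	C,D	8	614.12
Hard	SoxR	2zhg	2.80	a.6.1.3	A,D	homodimer	B,C	6	869.73
Hard	Engrailed homeodomain	3hdd	2.20	a.4.1.1	A	monomer	C,D	4	524.73
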
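block	name	pdb_id	resolution	scop	protein_chains	oligo_state	dna_chains	nrbc	unbound_pdb	unbound_resolution	unbound_chains	rmsd_u	rmsd_c
Easy	CopG repressor	1b01	2.56	a.43.1.3	A,B	homodimer	E,F	5	2cpg	1.60	A,B	0.511	0.460
Easy	PhoB	1gxp	2.50	a.4.6.1	A	monomer	C,D	7	1gxq	2.00	A	1.622	1.622
Easy	AML1 Runt domain	1hjc	2.65	b.2.5.6	D	monomer	E,F	6	1ean	1.70	A	1.056	1.056
Easy	Papillomavirus E2	1jj4	2.40	d.58.8.1	A,B	heterodimer	C,D	10	1f9f	1.90	C,D	0.949	1.484
Easy	TATA-binding protein	1qn4	1.86	d.129.1.1	B	monomer	E,F	15	1vok	2.10	B	0.934	0.934
Easy	Tet repressor	1qpi	2.50	a.4.1.9	A,C	homodimer	B,M	14	2tct	2.10	A,B	2.061	1.359
Easy	MtaN	1r8d	2.70	a.6.1.3	A,B	homodimer	C,D	8	1jbg	2.75	A,B	2.107	1.368
Easy	Sigma subunit domain 4	1rio	2.30	a.4.13.2	H	monomer	U,T	6	1ku3	1.80	A	1.405	1.405
Easy	MecI	1sax	2.80	a.4.5.39	A,B	homodimer	C,D	12	1okr	2.40	A,B	1.718	1.586
Easy	CAP	2cgp	2.20	a.4.5.4	A,F	homodimer	B,C,D,E	10	1i5z	1.90	A,B	1.652	1.919
Easy	LRP/ASNC family protein	2e1c	2.10	a.4.5.32	A,F	homodimer	B,D	12	2zny	2.59	A,B	1.339	1.184
Easy	IdeR	2it0	2.60	a.4.5.24	C,D	homodimer	E,F	11	2isy	1.96	A,B	0.476	0.489
Easy	Phi 434 repressor	2or1	2.50	a.35.1.2	R,L	homodimer	A,B	17	1r69	2.00	A,B	0.570	0.493
Easy	PutA	2rbf	2.25	NA	A,B	homodimer	C,D	8	2gpe	1.90	A,B	0.798	0.571
Easy	SoxR	2zhg	2.80	a.6.1.3	A,D	homodimer	B,C	6	2zhh	3.20	A,B	1.749	1.467
Easy	Controller protein	3clc	2.80	a.35.1.3	C,D	homodimer	E,F	14	3fya	3.00	A,B	0.834	0.809
Easy	CprK	3e6c	1.80	a.4.5.4	C,D	homodimer	A,B,E,F	12	3e5u	1.83	A,B	1.060	0.906
Easy	NrtR	3gz6	2.90	NA	A,B	homodimer	C,D	15	3gz5	2.20	A,B	0.853	0.726
Hard	Max	1an2	2.90	a.38.1.1	A,C	homodimer	B,D	10	1r05	NA	A,B	8.074	4.767
Hard	RXR-alpha	1by4	2.10	g.39.1.2	A,B	homodimer	E,F	8	1rxr	NA	A,B	4.637	2.326
Hard	Met repressor	1cma	2.80	a.43.1.5	A,B	homodimer	C,D	4	1cmc	1.80	A,B	2.232	2.313
Hard	Myb	1h8a	2.23	a.4.1.3	C	monomer	D,E	8	1gv2	1.68	A	9.153	9.153
Hard	QacR	1jt0	2.90	a.4.1.9	B,D	homodimer	E,F	12	1jt6	2.54	D,E	2.924	1.650
Hard	Lambda repressor	1lmb	1.80	a.35.1.2	3,4	homodimer	1,2	10	1lrp	3.20	A,B	32.342	0.928
Hard	Trp repressor	1tro	1.90	a.4.12.1	A,C	homodimer	I,J	12	1p6z	1.67	N,R	3.095	1.427
Hard	Prospero	1xpx	2.80	a.4.1.1	A	monomer	C,D	3	1mij	2.05	A	0.519	0.519
Hard	OhrR	1z9c	2.64	a.4.5.28	C,D	homodimer	I,J	12	1z91	2.50	A,B	2.521	1.919
Hard	Put3	1zme	2.50	g.38.1.1	C,D	homodimer	A,B	5	1ajy	NA	A,B	9.326	8.725
Hard	Phi lambda phage cII	1zs4	1.70	a.35.1.9	A,B,C,D	homotetramer	U,T	14	1zpq	2.80	A,B,C,D	4.947	2.679
Hard	p53	2ac0	1.80	b.2.5.2	A,B,C,D	homotetramer	E,F,G,H	21	2j1y	1.69	A,B,C,D	25.325	0.932
Hard	Omega repressor	2bnw	2.45	a.43.1.4	A,B	homodimer	E,F	4	1irq	3.50	A,B	0.887	1.049
Hard	ILF	2c6y	2.40	a.4.5.14	A	monomer	C,D	8	1jxs	NA	A	2.830	2.830
Hard	Phi 29 protein p4	2fio	2.70	NA	A,B	homodimer	C,D	4	2fip	2.00	C,D	0.679	0.496
Hard	IRF-2	2irf	2.20	a.4.5.23	L	monomer	C,D	6	1irf	NA	A	3.459	3.459
Hard	CgmR	2yvh	2.50	NA	C,D	homodimer	E,F,G,H	10	2yve	1.40	A,B	2.663	1.599
Hard	HipB	3dnv	2.68	NA	B,C	homodimer	E,T	10	2wiu	2.35	B,D	3.511	2.925
Hard	Engrailed homeodomain	3hdd	2.20	a.4.1.1	A	monomer	C,D	4	1enh	2.10	A	0.716	0.716
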
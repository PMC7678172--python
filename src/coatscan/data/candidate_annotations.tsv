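chrom	pos	ref	alt	gene	accession	cdna_pos	codon_ref	codon_alt	aa_sub
13	51640322	C	T	ATRN	NM_173995.3	1573	Gat	Aat	p.D525N
23	41483931	G	C	DTNBP1	NM_001045947.1	871	Gcc	Ccc	p.A291P
26	22870530	A	G	ELOVL3	NM_001192306.1	73	Aac	Gac	p.N25D
12	23298094	C	T	FREM2	XM_002691799.5	9260	aGg	aAg	p.R3087K
12	23336198	G	T	FREM2	XM_002691799.5	6042	gaC	gaA	p.D2014E
17	71465091	T	C	GGT1	NM_001206214.1	100	Agc	Ggc	p.S34G
28	4036781	G	A	GNPAT	NM_001103286.1	1462	Gtt	Att	p.V488I
X	37080066	C	T	L1CAM	NM_001192435.1	2722	Ggg	Agg	p.G908R
28	8475854	A	C	LYST	NM_174020.2	5337	ttA	ttC	p.L1779F
18	14705518	T	C	MC1R	NM_174108.2	143	cTg	cCg	p.L48P
11	103981017	T	G	NOTCH1	XM_024999642.1	43	Aca	Cca	p.T15P
3	13984639	T	C	NTRK1	XM_024989930.1	55	Agg	Ggg	p.R19G
5	57353185	T	C	PMEL	NM_001080215.2	1873	Tgg	Cgg	p.W625R
14	429568	A	G	RECQL4	NM_001098037.2	370	Acc	Gcc	p.T124A
14	429631	T	C	RECQL4	NM_001098037.2	433	Tca	Cca	p.S145P
4	40075565	G	A	SEMA3C	NM_001101082.1	718	Gtg	Atg	p.V240M
3	14622613	C	G	SEMA4A	NM_001075440.1	320	aGt	aCt	p.S107T
X	133162026	G	T	SHROOM2	XM_002700461.5	3176	gCc	gAc	p.A1059D
X	133162029	G	A	SHROOM2	XM_002700461.5	3173	tCc	tTc	p.S1058F
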
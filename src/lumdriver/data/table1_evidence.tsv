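sample_id	gene	variant_label	cgc	ccgd_ranks	functional_domain	same_variant_bc	same_variant_other	freq_all_cancers	freq_bc	consequence	fathmm	polyphen	sift	gvgd	chasm_p	km_significant	literature	printed_total	printed_label
401	MTHFD2	p.P17L c.50C>T	No	D,NR	No	No	No	0.0010	0.0005	missense	Pathogenic	Benign	Tolerated	C65	0.2851	Yes	Yes	2.5	pd
401	SEMA6D	p.E553A c.1658A>C	No	B	No	No	No	0.0084	0.0078	missense	Pathogenic	ND	Tolerated	C65	0.3967	Yes	Yes	3	pd
402	CACNA1E	p.R590W c.1768C>T	No	ND	Yes	No	Yes	0.0240	0.0255	missense	Pathogenic	Deleterious	Not Tolerated	C65	0.0523	No	Yes	3	pd
402	CIITA	p.P443T c.1327C>A	Yes	ND	Yes	No	No	0.00005	0.0	missense	Pathogenic	Deleterious	Tolerated	C35	0.3563	No	Yes	4.5	CGC
402	FAM65B/RIPOR2	p.E718D c.2154G>C	No	C	No	No	No	0.0035	0.0033	missense	Neutral	ND	Tolerated	C35	0.8042	No	No	1	Neutral
402	HECW2	p.D265G c.794A>G	No	D	Yes	No	No	0.0111	0.0086	missense	Pathogenic	Deleterious	Not Tolerated	C65	0.058	No	Yes	3	pd
402	NES	p.E340V c.1019A>T	No	ND	No	No	No	0.0092	0.0079	missense	Pathogenic	Deleterious	Not Tolerated	C65	0.1896	Yes	Yes	3	pd
402	PIK3CA	p.E545K c.1633G>A	Yes	B,C,D	Yes	Yes	Yes	0.0956	0.2664	missense	Pathogenic	Deleterious	Tolerated	C55	0.0002	No	Yes	7.5	CGC
402	SMURF2	p.S193C c.578C>G	No	A,C,D	No	No	No	0.0030	0.0039	missense	Pathogenic	Benign	Not Tolerated	C65	0.4405	No	Yes	4	PD
402	STAB1	p.G1381R c.4141G>A	No	ND	No	No	No	0.0134	0.0106	missense	Pathogenic	Deleterious	Tolerated	C65	0.6908	No	Yes	2.5	pd
402	ZNF462	p.G2426C c.7276G>T	No	C	No	No	No	0.0148	0.0168	missense	Pathogenic	Deleterious	Tolerated	C65	0.0004	Yes	No	2.5	pd
404	CILP2	p.R472G c.1414C>G	No	D	No	No	No	0.0083	0.0023	missense	Neutral	Deleterious	Not Tolerated	C65	0.661	No	No	1.5	Neutral
404	ELMO3	p.L251F c.753G>C	No	ND	No	No	No	0.0031	0.0009	missense	Pathogenic	Benign	Tolerated	C15	0.0675	Yes	Yes	2	pd
404	NOL9	p.S283* c.848C>G	No	ND	No	No	No	0.0030	0.0023	nonsense	Neutral	ND	ND	ND	ND	No	No	1.5	Neutral
406	C2orf57/TEX44	p.T265M c.794C>T	No	D	No	No	Yes	0.0024	0.0005	missense	Neutral	Benign	Tolerated	C65	0.5572	No	No	0.5	Neutral
406	IL22	p.R73C c.217C>T	No	ND	Yes	No	No	0.0016	0.0014	missense	Pathogenic	Deleterious	Not Tolerated	C65	0.6159	No	Yes	2.5	pd
406	OSR2	p.G262E c.785G>A	No	ND	Yes	No	No	0.0026	0.0024	missense	Pathogenic	Deleterious	Not Tolerated	C65	0.0922	No	Yes	2.5	pd
406	PIK3CA	p.H1047R c.3140A>G	Yes	B,C,D	Yes	Yes	Yes	0.0956	0.2664	missense	Pathogenic	Deleterious	Tolerated	C25	0.0	No	Yes	7.5	CGC
406	POC5	p.R541Q c.1622G>A	No	ND	No	No	No	0.0023	0.0014	missense	Pathogenic	Deleterious	Not Tolerated	C35	0.4111	No	No	1	Neutral
406	PRKAR1A	p.L20F c.58C>T	Yes	B,D	Yes	No	No	0.0028	0.0034	missense	Pathogenic	Benign	Tolerated	C15	0.3232	No	Yes	6	CGC
406	TP53	p.T220C c.659A>G	Yes	A,C,NR	Yes	Yes	Yes	0.2437	0.2387	missense	Pathogenic	Deleterious	Not Tolerated	ND	0.0012	Yes	Yes	9	CGC
413	AK8	p.T101P c.301A>C	No	B	Yes	No	No	0.0028	0.0014	missense	Neutral	Benign	Tolerated	C35	0.7606	No	No	2	pd
413	PLA2G4D	p.S173G c.517A>G	No	D	No	No	No	0.0053	0.0047	missense	Neutral	Benign	Tolerated	C55	0.3458	ND	No	0.5	Neutral
413	POLD1	p.P146R c.437C>G	Yes	ND	Yes	No	No	0.0070	0.0042	missense	Pathogenic	Deleterious	Not Tolerated	C65	0.1793	Yes	Yes	6.5	CGC
413	RSBN1	p.P148S c.442C>T	No	B,C,D	No	No	No	0.0040	0.0052	missense	Neutral	Deleterious	Not Tolerated	C65	0.1256	Yes	No	4	PD
413	SLC13A1	p.R277P c.830G>C	No	ND	No	No	No	0.0064	0.0070	missense	Neutral	Benign	Tolerated	C65	0.6497	No	No	0	Neutral
413	ZNF33A	p.G183V c.548G>T	No	ND	No	No	No	0.0044	0.0019	missense	Neutral	ND	ND	ND	0.3098	Yes	No	0	Neutral
415	LRRC66	p.H434N c.1300C>A	No	ND	No	No	No	0.0074	0.0033	missense	Neutral	Benign	Tolerated	C65	0.577	Yes	No	0	Neutral
415	MAMLD1	p.A775V c.2324C>T	No	C,NR	No	No	No	0.0046	0.0079	missense	Neutral	ND	Tolerated	C65	0.7952	No	No	1	Neutral
415	PIK3AP1	p.Q285K c.853C>A	No	A,C,NR	Yes	No	No	0.0051	0.0033	missense	Pathogenic	Deleterious	Not Tolerated	C45	0.1641	No	Yes	4.5	PD
415	PIK3CA	p.H1047L c.3140A>T	Yes	B,C,D	Yes	Yes	Yes	0.0956	0.2664	missense	Pathogenic	Benign	Tolerated	C65	0.0	No	Yes	7.5	CGC
415	PRKD1	p.Y800C c.2399A>G	No	ND	Yes	No	No	0.0085	0.0046	missense	Pathogenic	Deleterious	Not Tolerated	C65	0.0002	No	Yes	2.5	pd
415	TTC21B	p.R898* c.2692C>T	No	ND	No	No	No	0.0061	0.0061	nonsense	Pathogenic	ND	ND	ND	ND	No	No	1.5	Neutral
416	FAM96A	p.E75K c.223G>A	No	NR	Yes	No	No	0.0010	0.0009	missense	Pathogenic	Benign	Tolerated	C55	0.6908	Yes	Yes	1.5	Neutral
416	FLG	p.R1166C c.3496C>T	No	ND	No	No	Yes	0.0387	0.0364	missense	Neutral	ND	Not Tolerated	C65	0.6299	No	Yes	1.5	Neutral
416	GRIN1	p.Q910* c.2728C>T	No	NR	No	No	No	0.0043	0.0033	nonsense	Pathogenic	ND	ND	ND	ND	No	Yes	2.5	pd
416	MYO1H	p.E501G c.1502A>G	No	ND	Yes	No	No	0.0063	0.0076	missense	Pathogenic	ND	Tolerated	C65	0.0825	No	No	0.5	Neutral
416	TTN	p.L6228S c.18683T>C	No	B	Yes	No	No	0.1192	0.1368	missense	Pathogenic	Deleterious	ND	ND	0.1523	Yes	Yes	4.5	PD
417	AZI2	p.I66V c.196A>G	No	ND	No	No	No	0.0017	0.0023	missense	Pathogenic	Benign	Tolerated	C25	0.2633	Yes	No	0	Neutral
417	GRHL2	p.E32* c.94G>T	No	D	No	No	No	0.0046	0.0079	nonsense	Pathogenic	ND	ND	ND	ND	No	Yes	3	pd
417	NDST4	p.V313F c.937G>T	No	ND	Yes	No	No	0.0108	0.0028	missense	Pathogenic	Deleterious	Not Tolerated	C45	0.0601	No	Yes	2.5	pd
417	PRICKLE2	p.P81L c.242C>T	No	D	Yes	No	No	0.0057	0.0037	missense	Pathogenic	Deleterious	Not Tolerated	C65	0.0751	No	Yes	3	pd
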
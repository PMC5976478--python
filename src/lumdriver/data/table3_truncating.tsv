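sample_id	truncating_genes	n_truncating	ccgd_a	ccgd_b	expr_genes	n_expr	n_variants_sample
415	TTC21B	1	-	-	-	0	6
416	GRIN1	1	-	-	GRIN1	1	5
417	GRHL2	1	-	-	GRHL2	1	4
BRV-01	CTCFL;FAM118B;MARVELD2;VPS11	4	-	-	CTCFL	1	28
PD-02	PTEN	1	PTEN	-	PTEN	1	17
PD-04	FSCB;IL12RB2;AKAP11	3	-	-	-	0	55
PD-05	ATR;VIM;HK1;OR7C1;RBM16/SCAF8	5	ATR;RBM16/SCAF8	-	VIM	1	36
PD-06	CACNA2D3;DNAH17;PEX5L;MAB21L3;SYNE1;ZMYND11	6	-	ZMYND11;DNAH17	-	0	76
PD-07	PTRH1	1	-	-	-	0	13
PD-08	KCNJ15;SYTL2;ENSG00000233280	3	-	-	-	0	41
PD-09	PLCG2;SHCBP1;GATA3	3	PLCG2	GATA3	GATA3	1	15
PD-10	NEMF	1	-	NEMF	-	0	17
PD-11	KRTAP2-1;SLC2A3;NARG2/ICE2;COL22A1	4	-	-	NARG2/ICE2	1	16
PD-12	GATA3;PDE7A	2	-	GATA3	GATA3	1	22
TCGA-01	ABCA10;NTRK2;MAP3K6;CX3CR1;KBTBD4;KMT2A	6	-	-	KMT2A;NTRK2	2	46
TCGA-02	GATA3;DALRD3;RASGRP2;SALL3;TNFSF9	5	-	GATA3	GATA3	1	18
TCGA-03	C1orf187;NR1I3;FAM155A;GNAS;PCDHA2;SSC5D;SEC14L5;WDR81	8	-	-	NR1I3	1	21
TCGA-04	-	41	UBR5	BTBD7;ITGB1;KLHDC2;MTA2;ODF2;PCCA;PPFIA3;RASGRF1	ITGA8;MTA2;NFKBIA;ATF7IP;SPAG8;TARBP2;TLR3	7	546
TCGA-05	NMS;FAM111B;DYNC2H1	3	-	-	-	0	31
TCGA-06	ARID1A;CFTR;SYNM;GATA3;CCDC61;CDK18;IRF7;TCF20;KIAA0430/MARF1;LZTR1;MAP2K4;SH3PXD2A	12	ARID1A;TCF20;CFTR;MAP2K4;SH3PXD2A	GATA3	ARID1A;GATA3;IRF7;TCF20	4	48
TCGA-07	GATA3	1	-	GATA3	GATA3	1	21
TCGA-08	-	73	ATXN2;DIP2B;KIAA2026;PCNX1;PHF2;TNKS2;SLC9A1	CLMN;KIAA0947/ICE1;OSBPL1A;RAB11A;ARHGAP29;SLTM	-	17	229
TCGA-09	DYNC1H1;IGSF3;MAST1;AKAP12;ASB10;NASP;TENM1/ODZ1;THOC5;ZNF799	9	-	THOC5	THOC5	1	35
TCGA-10	C9orf66	1	-	-	-	0	9
TCGA-11	A2M;CHKB;NBR1;RB1;SYT3;ARR3;KIFC3;PPP1R3C;ZBTB24	9	RB1	NBR1	RB1	1	84
TCGA-12	EFEMP1;MAP2K4;C1orf35;KIF26A	4	MAP2K4	-	-	0	15
TCGA-13	SNUPN;GATA3;GRM6	3	-	GATA3	GATA3	1	13
TCGA-14	PRDM5;COL14A1;POLA1;SLC22A25	4	-	PRDM5	-	0	79
TCGA-15	IGSF1;NFYB;SCN2A;TRAF5	4	-	NFYB	NFYB;TRAF5	2	34
TCGA-16	JHDM1D/KDM7A	1	-	-	JHDM1D/KDM7A	1	30
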
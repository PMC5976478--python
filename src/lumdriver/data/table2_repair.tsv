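sample_id	gene	mechanisms	n_variants_sample
406	TP53	DDC	7
413	POLD1	BER,NER,MMR	6
PD-02	FANCD2	HRR	17
PD-04	POLD1	BER,NER,MMR	55
PD-04	TP53	DDC	55
PD-05	ATR	NHEJ,DDC	36
PD-06	FANCL	HRR	76
PD-10	BAP1	HRR	17
PD-11	TP53	DDC	16
TCGA-01	PARP4	BER	46
TCGA-04	MUTYH	BER	546
TCGA-04	ERCC6	NER	546
TCGA-04	PALB2	HRR	546
TCGA-06	PARP4	BER	48
TCGA-07	POLE	BER,NER,MMR	21
TCGA-08	MLH1	MMR	229
TCGA-08	RAD9A	HRR	229
TCGA-10	TP53	DDC	9
TCGA-11	TP53	DDC	84
TCGA-11	RAD51	HRR	84
TCGA-14	POLQ	TLS	79
TCGA-14	TP53	DDC	79
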
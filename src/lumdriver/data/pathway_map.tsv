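gene	mechanisms
TP53	DDC
POLD1	BER,NER,MMR
POLE	BER,NER,MMR
FANCD2	HRR
FANCL	HRR
BAP1	HRR
PALB2	HRR
RAD9A	HRR
RAD51	HRR
ATR	NHEJ,DDC
PARP4	BER
MUTYH	BER
ERCC6	NER
MLH1	MMR
POLQ	TLS
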